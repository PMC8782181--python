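Caf40
Cdc12
Cdc73
Chs5
Clu1
Dcp1
Dcp2
Def1
Dhh1
Edc3
eIF2A
eIF4G1
Gas5
Gbp2
Hek2
Hel2
Hnm1
Lcp5
Lsm1
Lsm4
Lsm12
Meu1
Mkt1
Mrh1
Nam7
Nrp1
Pab1
Pat1
Pbp1
Pbp2
Pbp4
Pma2
Pop2
Rnq1
Rrp3
Sbp1
Scd6
Scp160
Snq2
Sro9
Svl3
Syh1
Ubp3
Whi4
Xrn1
Yck2
Yro2
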