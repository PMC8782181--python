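Bfr1
Bre5
Bsp1
Bud7
Cdc12
Cdc39
Chs5
Cic1
Clu1
Cop1
Coy1
Dcp2
Ded1
Def1
Dhh1
Ecm32
Ecm33
Edc3
eIF2A
eIF3g
eIF3i
eIF4G1
eIF4G2
Fun12
Gas1
Gas5
Gbp2
Hek2
Hel2
Hnm1
Hxt1
Ist2
Lcp5
Lsm1
Lsm12
Map1
Meu1
Mis1
Mkt1
Mrn1
Nat1
Nce102
Nop12
Nop4
Nrp1
Pab1
Pbp1
Pbp2
Pbp4
Phb1
Pil1
Pma1
Pma2
Pop2
Pub1
Puf3
Puf4
Rbg1
Rho1
Rie1
Rnq1
Rrb1
Rrp3
Sbp1
Scd6
Scp160
Sec1
Sec27
Sgn1
Snq2
Srp54
Srp68
Ssh1
Sui3
Sup35
Sur7
Svl3
Syh1
Tat1
Ubp3
Whi2
Whi4
Yck2
Yro2
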