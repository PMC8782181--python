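Brx1
Bsp1
Bud7
Cdc73
Enp2
Gar1
Hnm1
Lsm12
Mkt1
Nma1
Nop1
Osh6
Pbp1
Pbp2
Pbp4
Puf3
Puf6
Rpf2
Rpb2
Rpn5
Rrb1
Ssh1
Svl3
Syh1
Tat1
Utp22
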