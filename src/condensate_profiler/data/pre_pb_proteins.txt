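Cic1
Dcp1
Dcp2
Edc3
Rpc19
Smi1
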