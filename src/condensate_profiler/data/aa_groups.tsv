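# named amino-acid property groups: name<TAB>residues
aromatic	FWY
hydrophobic_kd	ACFILMV
flexible_vihinen	DEGKNPQRS
disorder_promoting	AEGKPQRS
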