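# name	formal_charge	cross_sectional_area_A2
POPC	0	70
POPG	-1	70
TOCL	-2	130
MLCL	-2	110
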