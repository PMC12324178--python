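# 10x Genomics 3' v3 single-cell layout (adapter literals: partial Read1/TSO)
ADAPTER5	fixed_sequence	CTACACGACGCTCTTCCGATCT
CBC	random_fixed_length	N{16}
UMI	random_fixed_length	N{12}
POLYT	homopolymer	T 10-60
CDNA	variable_length	100-500
ADAPTER3	fixed_sequence	CCCATGTACTCTGCGTTGATACCACTGCTT
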