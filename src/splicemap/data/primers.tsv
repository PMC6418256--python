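# Validation primer pairs for cDNA and gDNA amplification of the two
# candidate splice-donor loci plus a B2M RT-PCR control.
name	forward	reverse	expected_size	annealing_t
cDNA_MLPH_ex6-9	TTTGAGGCTGACTCTGACGA	CCTCCTGAGGGTCTCCTCTT	486	60.0
gDNA_MLPH_ex7	CCTCCAGAAGAGCAGATGG	GAGCTATTGATGCTGGGACT	335	58.0
cDNA_MITF_ex1M-2	CTTCTCTATGCCCGTCAGTC	GGTTGGCATGTTTATTTGCT	241	57.5
gDNA_MITF_ex1M	CTTCTCTATGCCCGTCAGTC	GAACAGGAGCTGATGGAGAG	368	58.0
cDNA_B2M_ex1-2	TTCTCTGGACGTTGGTCTTC	GAAACTCCAGTCCTTGCTGA	236	58.0
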