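# MLPH donor-site variant (G>A) genotyping counts by coat phenotype and population.
# Carrier rows are phenotypes whose genotype shorthand includes homozygous p/p.
# Note: the published standard-dark-brown row prints run-together digits; the
# transcription 10 hom_ref / 2 het / 0 hom_alt is the split consistent with the
# printed row total of 12.
phenotype	population	carrier	n_hom_ref	n_het	n_hom_alt
standard_dark_brown	novosibirsk	false	10	2	0
k/k	novosibirsk	false	0	2	0
b/b	novosibirsk	false	1	1	0
m/m	novosibirsk	false	1	0	0
a/a m/m	novosibirsk	false	1	0	0
p/p	novosibirsk	true	0	0	7
p/p	tver	true	0	0	10
k/k p/p	novosibirsk	true	0	0	2
m/m a/a p/p	novosibirsk	true	0	0	1
SH/+ p/p	novosibirsk	true	0	0	2
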