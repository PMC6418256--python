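# MITF-M donor-site variant (G>A) genotyping counts by coat phenotype and population.
# Carrier rows are the h/h (white) phenotype groups.
phenotype	population	carrier	n_hom_ref	n_het	n_hom_alt
standard_dark_brown	novosibirsk	false	8	1	0
k/k	novosibirsk	false	2	0	0
b/b	novosibirsk	false	2	0	0
m/m	novosibirsk	false	0	1	0
a/a m/m	novosibirsk	false	1	0	0
p/p	novosibirsk	false	5	1	0
k/k p/p	novosibirsk	false	2	0	0
m/m a/a p/p	novosibirsk	false	1	0	0
SH/+ p/p	novosibirsk	false	2	0	0
h/h	novosibirsk	true	0	0	12
h/h	tver	true	0	0	4
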