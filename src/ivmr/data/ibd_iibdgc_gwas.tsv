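rsid	chrom	locus	effect_allele	other_allele	eaf	or	ci_low	ci_high	pvalue
rs385076	2	NLRC4	C	T	0.64	1.05	1.02	1.09	0.005
rs17229943	5	OCLN	C	T	0.05	1.07	0.97	1.18	0.066
rs71478720	11	IL18	C	T	0.76	1.05	1.01	1.09	0.012
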