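rsid	chrom	locus	effect_allele	other_allele	eaf	beta	pvalue
rs385076	2	NLRC4	C	T	0.64	0.243	1.7e-22
rs17229943	5	OCLN	C	T	0.05	0.312	1.6e-11
rs71478720	11	IL18	C	T	0.76	0.267	3.1e-22
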