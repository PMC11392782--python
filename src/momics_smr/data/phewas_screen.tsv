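gene_id	disease	snp	ea	oa	or_xy	ci_low	ci_high	fdr
TUFM	Obesity	rs7187776	G	A	1.084	1.049	1.119	6.33e-4
TUFM	Overweight	rs7187776	G	A	1.081	1.047	1.117	6.33e-4
TUFM	Varicose veins	rs7187776	G	A	1.078	1.044	1.114	9.48e-4
TUFM	Rheumatoid arthritis	rs7187776	G	A	1.089	1.037	1.143	9.50e-2
MCL1	Nasal polyps	rs41272019	T	C	0.586	0.469	0.732	2.04e-3
ACADVL	Non-epithelial cancer of skin	rs507506	G	A	0.326	0.185	0.576	2.99e-2
ACADVL	Essential hypertension	rs507506	G	A	0.494	0.379	0.643	6.61e-5
ACADVL	Nonspecific chest pain	rs507506	G	A	0.526	0.369	0.749	7.17e-2
SLC25A13	Disorders of the pituitary gland and its hypothalamic control	rs17167473	A	G	1.850	1.304	2.625	7.36e-2
SLC25A13	Neutropenia	rs17167473	A	G	0.747	0.634	0.879	7.36e-2
SLC25A13	Arthropathy	rs17167473	A	G	0.912	0.865	0.961	7.36e-2
SLC25A13	Degeneration of intervertebral disc	rs17167473	A	G	0.713	0.598	0.849	5.82e-2
SLC25A13	Symptoms and disorders of the joints	rs17167473	A	G	0.740	0.636	0.860	5.82e-2
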