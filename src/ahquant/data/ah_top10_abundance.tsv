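accession	description	gene	ibaq	percentage
P23471	Receptor-type tyrosine-protein phosphatase zeta	PTPRZ1	6.79E+07	29.60
P02768	Serum albumin	ALB	2.30E+08	27.34
P02787	Serotransferrin	TF	4.99E+07	6.59
P01859	Immunoglobulin heavy constant gamma 2	IGHG2	7.07E+07	4.35
P08185	Corticosteroid-binding globulin	SERPINA6	4.29E+07	3.31
P01834	Immunoglobulin kappa constant	IGKC	9.58E+07	1.93
P07288	Prostate-specific antigen	KLK3	3.55E+07	1.75
P41222	Prostaglandin-H2 D-isomerase	PTGDS	3.65E+07	1.32
P02763	Alpha-1-acid glycoprotein 1	ORM1	2.64E+07	1.06
P02766	Transthyretin	TTR	2.18E+07	0.59
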