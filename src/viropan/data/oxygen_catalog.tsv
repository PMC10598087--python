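pfam_id	enzyme_family	cofactor	pfam_clan
PF00268	R2 subunit ribonucleotide reductase type Ia (R2RnR)	Fe	CL0044
PF04777	Erv1/Alr family sulfhydryl oxidase	FAD	-
PF04805	Poxvirus sulfhydryl oxidase (Erv1/Alr-like)	FAD	-
PF13532	2OG-Fe(II) oxygenase superfamily (2OGX)	Fe(II)	CL0029
PF13640	2OG-Fe(II) oxygenase superfamily (2OGX)	Fe(II)	CL0029
PF13759	2OG-Fe(II) oxygenase superfamily (2OGX)	Fe(II)	CL0029
PF00080	Cu/Zn superoxide dismutase	Cu/Zn	-
PF00487	Fatty acid desaturase	Fe	CL0713
PF04116	Fatty acid hydroxylase superfamily	-	CL0713
PF05118	Aspartyl/Asparaginyl beta-hydroxylase	-	CL0029
PF05995	Cysteine dioxygenase	Fe(II)	CL0029
PF05721	Phytanoyl-CoA dioxygenase	Fe(II)	CL0029
PF03067	Lytic polysaccharide mono-oxygenase	-	CL0159
PF00173	Cytochrome b5-like heme/steroid-binding domain	Heme	-
PF08417	Pheophorbide A oxygenase	Fe	CL0209
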