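# Synthetic example Pfam -> COG-category map for testing and demonstration.
# Letters are plausible functional assignments, not authoritative database
# annotations; real analyses should supply their own curated table.
pfam_id	category
PF00268	F
PF04777	O
PF04805	O
PF13532	L
PF13640	L
PF13759	L
PF00080	P
PF00487	I
PF04116	I
PF05118	O
PF05995	E
PF05721	I
PF03067	G
PF00173	C
PF08417	H
PF00136	L
PF00176	K
PF01443	L
PF04851	L
PF03237	Vc
PF00910	L
PF02867	F
PF00692	F
PF04717	L
PF01048	F
PF03013	T
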