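pathway	category	mode	clause_index	alternatives	negated
nitrogen_fixation	nitrogen	clauses	1	nifH	0
nitrogen_fixation	nitrogen	clauses	2	nifD	0
nitrogen_fixation	nitrogen	clauses	3	nifK	0
denitrification	nitrogen	clauses	1	narG|napA	0
denitrification	nitrogen	clauses	2	nirK|nirS	0
denitrification	nitrogen	clauses	3	norB	0
denitrification	nitrogen	clauses	4	nosZ	0
dnra	nitrogen	clauses	1	nrfA	0
partial_nitrification	nitrogen	clauses	1	hao	0
partial_nitrification	nitrogen	clauses	2	amoA	1
anammox	nitrogen	clauses	1	hzo	0
sulfate_reduction	sulfur	clauses	1	dsrA	0
sulfate_reduction	sulfur	clauses	2	dsrB	0
sulfate_reduction	sulfur	clauses	3	aprA	0
sulfate_reduction	sulfur	clauses	4	sat	0
sulfur_oxidation	sulfur	clauses	1	soxB	0
sulfur_oxidation	sulfur	clauses	2	soxAX	0
sulfur_oxidation	sulfur	clauses	3	soxYZ	0
wood_ljungdahl	carbon_fixation	clauses	1	cooS|acsA	0
wood_ljungdahl	carbon_fixation	clauses	2	acsB	0
calvin	carbon_fixation	clauses	1	rbcL_I|rbcL_II_III|rbcL_III	0
methanogenesis_h2	methane	clauses	1	mcrA	0
methanogenesis_h2	methane	clauses	2	mtrA	0
methanogenesis_h2	methane	clauses	3	fwdA	0
rnf_complex	fermentation	clauses	1	rnfC	0
formate_dehydrogenase	fermentation	clauses	1	fdhA	0
fermentation	fermentation	count	1	ackA|pta|ldhA|adhE|pflB|porA	0
complex_carbon	complex_carbon	count	1	celA|cbhA|bglB|xynA|chiA|lacZ|amyA	0
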