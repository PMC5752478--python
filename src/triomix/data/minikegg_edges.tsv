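# pathway_id	member_a	member_b
# Hand-curated, undirected skeletons of the public KEGG-style pathway maps;
# reaction directionality is deliberately dropped.
tca	Citric acid	cis-Aconitic acid
tca	cis-Aconitic acid	Isocitric acid
tca	Isocitric acid	Oxoglutaric acid
tca	Oxoglutaric acid	Succinyl-CoA
tca	Succinyl-CoA	Succinic acid
tca	Succinic acid	Fumaric acid
tca	Fumaric acid	Malic acid
tca	Malic acid	Oxaloacetic acid
tca	Oxaloacetic acid	Citric acid
tca	Pyruvic acid	Acetyl-CoA
tca	Acetyl-CoA	Citric acid
tca	Pyruvic acid	Oxaloacetic acid
ala_asp_glu	L-Glutamic acid	L-Glutamine
ala_asp_glu	L-Aspartic acid	L-Asparagine
ala_asp_glu	L-Glutamic acid	L-Aspartic acid
ala_asp_glu	L-Glutamic acid	4-Aminobutanoic acid
ala_asp_glu	4-Aminobutanoic acid	Succinic semialdehyde
ala_asp_glu	L-Aspartic acid	N-Acetyl-L-aspartic acid
ala_asp_glu	L-Aspartic acid	Argininosuccinic acid
ala_asp_glu	L-Aspartic acid	Adenylosuccinic acid
ala_asp_glu	L-Glutamic acid	L-Alanine
bile_acid	Cholesterol	7alpha-Hydroxycholesterol
bile_acid	7alpha-Hydroxycholesterol	7alpha-Hydroxy-4-cholesten-3-one
bile_acid	7alpha-Hydroxy-4-cholesten-3-one	Cholic acid
bile_acid	7alpha-Hydroxy-4-cholesten-3-one	Chenodeoxycholic acid
bile_acid	Cholic acid	Taurocholic acid
bile_acid	Cholic acid	Glycocholic acid
bile_acid	Chenodeoxycholic acid	Taurochenodeoxycholic acid
bile_acid	Chenodeoxycholic acid	Glycochenodeoxycholic acid
purine	AMP	Adenosine
purine	Adenosine	Inosine
purine	Inosine	Hypoxanthine
purine	Hypoxanthine	Xanthine
purine	Xanthine	Uric acid
purine	AMP	IMP
purine	IMP	Inosine
purine	Cyclic AMP	AMP
purine	GMP	Guanosine
purine	Guanosine	Guanine
purine	Guanine	Xanthine
purine	Xanthosine	Xanthine
purine	Adenine	Adenosine
glycolysis	D-Glucose	Glucose 6-phosphate
glycolysis	Glucose 6-phosphate	Fructose 6-phosphate
glycolysis	Fructose 6-phosphate	Fructose 1,6-bisphosphate
glycolysis	Fructose 1,6-bisphosphate	Glyceraldehyde 3-phosphate
glycolysis	Glyceraldehyde 3-phosphate	3-Phosphoglyceric acid
glycolysis	3-Phosphoglyceric acid	2-Phosphoglyceric acid
glycolysis	2-Phosphoglyceric acid	Phosphoenolpyruvic acid
glycolysis	Phosphoenolpyruvic acid	Pyruvic acid
glycolysis	Pyruvic acid	L-Lactic acid
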