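tca	Citrate cycle (TCA cycle)	Citric acid	cis-Aconitic acid	Isocitric acid	Oxoglutaric acid	Succinyl-CoA	Succinic acid	Fumaric acid	Malic acid	Oxaloacetic acid	Pyruvic acid	Acetyl-CoA
ala_asp_glu	Alanine, aspartate and glutamate metabolism	L-Alanine	L-Aspartic acid	L-Glutamic acid	L-Glutamine	L-Asparagine	4-Aminobutanoic acid	Succinic semialdehyde	N-Acetyl-L-aspartic acid	Argininosuccinic acid	Adenylosuccinic acid
bile_acid	Primary bile acid biosynthesis	Cholesterol	7alpha-Hydroxycholesterol	7alpha-Hydroxy-4-cholesten-3-one	Cholic acid	Chenodeoxycholic acid	Taurocholic acid	Glycocholic acid	Taurochenodeoxycholic acid	Glycochenodeoxycholic acid
purine	Purine metabolism	Inosine	Hypoxanthine	Xanthine	Uric acid	Adenine	Adenosine	AMP	Cyclic AMP	IMP	GMP	Guanosine	Guanine	Xanthosine
glycolysis	Glycolysis / Gluconeogenesis	D-Glucose	Glucose 6-phosphate	Fructose 6-phosphate	Fructose 1,6-bisphosphate	Glyceraldehyde 3-phosphate	3-Phosphoglyceric acid	2-Phosphoglyceric acid	Phosphoenolpyruvic acid	Pyruvic acid	L-Lactic acid
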