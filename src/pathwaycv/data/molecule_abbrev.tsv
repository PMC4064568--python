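full_name	abbreviation
1D-myo-Inositol 1,3,4,5,6-pentakisphosphate	I(1,3,4,5,6)P5
4-(4-(dimethylamino)styryl)-N-methylpyridinium	4-Di-2-ASP
guanosine 5'-diphosphate	GDP
flavin adenine dinucleotide	FAD
adenosine 5'-triphosphate	ATP
adenosine 5'-diphosphate	ADP
4-aminobutanoic acid	GABA
sodium(1+)	Na+
hydron	H+
chloride	Cl-
alpha-D-mannose	Man
tetradecanoic acid	MYS
dolichyl phosphate D-mannose	DOLPM
N-acetylneuraminic acid	Neu5Ac
retinyl palmitate	RPALM
all-trans-retinol	atROL
prostaglandin H2	PGH2
prostaglandin D2	PGD2
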