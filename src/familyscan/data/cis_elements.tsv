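name	pattern	category	group
CAT-box	GCCACT	meristem expression	PDE
GCN4-motif	TGAGTCA	endosperm expression	PDE
RY-element	CATGCATG	seed-specific regulation	PDE
circadian	CAANNNNATC	circadian control	PDE
O2-site	GATGACATGG	zein metabolism regulation	PDE
MSA-like	TCTAACGGT	cell cycle regulation	PDE
G-box	CACGTG	light response	SE
Box4	ATTAAT	light response	SE
GT1-motif	GGTTAA	light response	SE
I-box	GATAAGR	light response	SE
TCT-motif	TCTTAC	light response	SE
MRE	AACCTAA	light response	SE
AE-box	AGAAACAA	light response	SE
ARE	AAACCA	anaerobic induction	SE
GC-motif	CCCCCG	anaerobic induction	SE
MBS	CAACTG	drought inducibility	SE
LTR	CCGAAA	low-temperature response	SE
TC-rich	ATTCTCTAAC	defense and stress response	SE
WUN-motif	AAATTTCCT	wound response	SE
MBSI	AAAAAACGGTTA	flavonoid biosynthesis regulation	SE
ABRE	ACGTG	abscisic acid response	HE
CGTCA-motif	CGTCA	methyl jasmonate response	HE
TGACG-motif	TGACG	methyl jasmonate response	HE
TCA-element	CCATCTTTTT	salicylic acid response	HE
GARE-motif	TCTGTTG	gibberellin response	HE
P-box	CCTTTTG	gibberellin response	HE
TATC-box	TATCCCA	gibberellin response	HE
TGA-element	AACGAC	auxin response	HE
AuxRR-core	GGTCCAT	auxin response	HE
ERE	ATTTCAAA	ethylene response	HE
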