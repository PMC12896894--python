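name	pattern	category	subcategory
HD-Zip 1	CAATWATTG	growth_development	palisade mesophyll differentiation
CAT-box	GCCACT	growth_development	meristem expression
W box	TTGACC	growth_development	senescence expression
as-1	TGACG	growth_development	shoot expression
GCN4_motif	TGAGTCA	growth_development	endosperm expression
AAGAA-motif	GAAAGAA	growth_development	endosperm expression
GARE-motif	TCTGTTG	phytohormone	gibberellin
P-box	CCTTTTG	phytohormone	gibberellin
TGA-element	AACGAC	phytohormone	auxin
AuxRR-core	GGTCCAT	phytohormone	auxin
TCA-element	CCATCTTTTT	phytohormone	SA
TCA	TCAGAAGAGG	phytohormone	SA
ERE	ATTTTAAA	phytohormone	ethylene
CGTCA-motif	CGTCA	phytohormone	MeJA
TGACG-motif	TGACG	phytohormone	MeJA
ABRE	ACGTG	phytohormone	ABA
ABRE3a	TACGTG	phytohormone	ABA
ABRE4	CACGTA	phytohormone	ABA
MYB	CAACCA	stress	MYB binding
MYC	CATTTG	stress	MYC binding
DRE	RCCGAC	stress	dehydration
LTR	CCGAAA	stress	low temperature
MBS	CAACTG	stress	drought
WUN-motif	AAATTTCCT	stress	wound
Box 4	ATTAAT	light	light response
G-box	CACGTG	light	light response
GT1-motif	GGTTAA	light	light response
TCT-motif	TCTTAC	light	light response
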