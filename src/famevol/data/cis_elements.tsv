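# Cis-acting regulatory element dictionary (IUPAC consensus strings curated from the
# plant promoter literature). Columns: element, iupac, category, subcategory.
element	iupac	category	subcategory
CGTCA-motif	CGTCA	phytohormone	MeJA
TGACG-motif	TGACG	phytohormone	MeJA
TCA-element	CCATCTTTTT	phytohormone	SA
SARE	TTCGACCATCTT	phytohormone	SA
ABRE	ACGTG	phytohormone	ABA
motif-IIb	CCGCCGCGCT	phytohormone	ABA
GARE-motif	TCTGTTG	phytohormone	GA
TATC-box	TATCCCA	phytohormone	GA
P-box	CCTTTTG	phytohormone	GA
AuxRR-core	GGTCCAT	phytohormone	IAA
TGA-element	AACGAC	phytohormone	IAA
ERE	ATTTCAAA	phytohormone	ethylene
HSE	AAAAAATTTC	stress	heat
TC-rich_repeats	GTTTTCTTAC	stress	defense
ARE	AAACCA	stress	anaerobic
GC-motif	CCCCCG	stress	anoxia
MBS	CAACTG	stress	drought
LTR	CCGAAA	stress	low_temperature
WUN-motif	AAATTTCCT	stress	wound
Skn-1_motif	GTCAT	development	endosperm
GCN4_motif	TGTGTCA	development	endosperm
CCGTCC-box	CCGTCC	development	meristem
circadian	CAANNNNATC	development	circadian
G-box	CACGTG	light	light
GAG-motif	AGAGAGT	light	light
GT1-motif	GGTTAA	light	light
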