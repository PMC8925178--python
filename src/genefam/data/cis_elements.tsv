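element	consensus	category
ABRE	ACGTG	phytohormone
CGTCA-motif	CGTCA	phytohormone
TGACG-motif	TGACG	phytohormone
TGA-element	AACGAC	phytohormone
AuxRR-core	GGTCCAT	phytohormone
TCA-element	CCATCTTTTT	phytohormone
GARE-motif	TCTGTTG	phytohormone
P-box	CCTTTTG	phytohormone
MBS	CAACTG	abiotic
LTR	CCGAAA	abiotic
TC-rich repeats	ATTTTCTTCA	abiotic
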