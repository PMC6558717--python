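# bbxkit cis-element library, version 1
# Literal/IUPAC consensus strings for the named plant cis-acting elements,
# compiled from the standard plant promoter-element literature.  Categories:
# development = plant growth & development, hormone = phytohormone response,
# stress = biotic/abiotic stress response.
name	consensus	category	function_note
Skn-1-motif	GTCAT	development	endosperm expression
GCN4_motif	TGAGTCA	development	endosperm expression
CAT-box	GCCACT	development	meristem expression
CCGTCC-box	CCGTCC	development	meristem-specific activation
O2-site	GATGATGTGG	development	zein metabolism regulation
MRE	AACCTAA	development	MYB binding site, light responsiveness
Box 4	ATTAAT	development	part of a light-responsive module
circadian	CAANNNNATC	development	circadian control
TGACG-motif	TGACG	hormone	MeJA responsiveness
ABRE	TACGTG	hormone	abscisic acid responsiveness
TGA-element	AACGAC	hormone	auxin responsiveness
AuxRR-core	GGTCCAT	hormone	auxin responsiveness
GARE-motif	TCTGTTG	hormone	gibberellin responsiveness
P-box	CCTTTTG	hormone	gibberellin responsiveness
TATC-box	TATCCCA	hormone	gibberellin responsiveness
ERE	ATTTCAAA	hormone	ethylene responsiveness
ARE	AAACCA	stress	anaerobic induction
Box-W1	TTGACC	stress	fungal elicitor responsiveness
HSE	AAAAAATTTC	stress	heat stress responsiveness
TC-rich repeats	GTTTTCTTAC	stress	defence and stress responsiveness
GC-motif	CCCCCG	stress	anoxia-specific inducibility
MBS	CAACTG	stress	MYB binding site, drought inducibility
LTR	CCGAAA	stress	low-temperature responsiveness
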