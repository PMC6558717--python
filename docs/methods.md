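# Methods

This note documents the models and procedures bbxkit implements, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions that were genuinely open.

## Family identification and domain architecture

B-BOX and CCT domains are recognized by anchor-residue patterns rather than
profile HMMs: the residues that define the domains biochemically — the
Cys/His scaffold that coordinates the two Zn ions of a B-BOX, the
basic-residue lattice of the CCT — are matched at family-typical spacings.

* **B-BOX1** is canonicalized as the anchor scaffold C, C, C, C/H, H, H
  with spacings `C-x(9,10)-C-x(6,10)-C-x(2,3)-[CH]-x(3,4)-H-x(5,10)-H`
  (five conserved Cys of which four are absolute, plus the His pair).
* **B-BOX2**: `C-x(2,4)-H-x(7,10)-C-x(1,4)-D-x(4,7)-C-x(2)-C-x(3,6)-H-x(2,5)-H`.
* **CCT**: the 42-residue consensus
  `R-x5-R-Y-x-E-K-x3-R-x3-K-x2-R-Y-x2-R-K-x2-A-x2-R-x-R-x-K-G-R-F-x-K`,
  matched at fixed offsets.  Real CCTs deviate from the consensus, so a
  match requires at least 80 % of the 19 anchors (configurable); demanding
  all of them would reject biological CCTs.

Scanning is N→C with deterministic overlap resolution (earliest start wins,
then the longest match, then pattern name), so outputs are reproducible.
Variable-gap patterns are matched by depth-first search preferring larger
gaps (the reported match is the longest at its start).

Architecture determines the clade by the standard rule table: ≥2 B-BOX +
CCT → I or II; 1 B-BOX + CCT → III; ≥2 B-BOX → IV; 1 B-BOX → V; no B-BOX →
excluded from the family.  Architecture alone cannot separate clades I and
II (they differ by B-BOX2 sequence divergence, a phylogenetic signal), so
without a tree placement the protein defaults to clade II and carries an
`architecture_only` flag.  A CCT N-terminal to every B-BOX is biologically
atypical and is flagged rather than classified.

Molecular weight uses average (isotope-weighted) residue masses plus one
water, matching the ExPASy convention; the isoelectric point is the root of
the Henderson–Hasselbalch net-charge function under the Bjellqvist pKa set
(side chains D/E/C/Y/H/K/R plus termini, with the residue-specific terminal
adjustments), found by bisection on [0, 14] to 1e-4 and reported to two
decimals.  Both are cross-checked against Biopython's independent
implementations in the test suite.

## Homology

At gene-family scale (tens of proteins), graph-clustering orthology
pipelines reduce to reciprocal best hits, so bbxkit implements RBH directly
over optimal global Needleman–Wunsch alignments (BLOSUM62, gap open 10,
extend 0.5, via Biopython's PairwiseAligner).  Identity is counted over the
aligned (both non-gap) columns; coverage is those columns over the shorter
sequence.  Calls require:

* **orthologs** — reciprocal best between-genome hits, alignment score > 0,
  identity ≥ 0.4 and coverage ≥ 0.5;
* **paralogs** — reciprocal best within-genome hits passing the same
  thresholds that additionally out-score *each* member's best
  between-genome hit (the in-paralog criterion: the two copies are closer
  to each other than to anything in the other genome).

Score ties reject both candidates rather than picking arbitrarily.  The
identity floor of 0.4 reflects a property of global alignment within a
domain-sharing family: any two members share the anchor residues, so
unrelated-pair identity concentrates near 0.28–0.36 — a floor of 0.3 sits
inside that noise band and would admit chance pairings, while every genuine
pair this pipeline is designed to call remains well above 0.5.

## Ka/Ks (Nei–Gojobori 1986 with Jukes–Cantor correction)

For each sense codon, every one of the nine single-nucleotide mutations is
classified as synonymous or nonsynonymous; mutations creating a stop codon
are excluded from the denominator, so each position contributes exactly one
site and S + N = 3 per codon.  Between two codons, the synonymous and
nonsynonymous difference counts are averaged over all orderings of the
differing positions, excluding pathways through stop codons (renormalizing
over the legal ones; a column with no legal pathway is skipped with a log
message).  Sites are averaged between the two sequences, proportions
ps = Sd/S and pn = Nd/N are corrected with d = −¾ ln(1 − 4p/3), and
p ≥ 3/4 flags the estimate as saturated (ratio undefined).  Gapped codon
columns are skipped; the trailing stop codon is excluded; estimates require
at least 10 ungapped codon columns.

Conventions fixed here and used consistently: the selection bins are
left-closed (<0.3 strong purifying; 0.3–1 inclusive of both endpoints
relaxed purifying; strictly >1 positive), and the duplication-age bounds
are Ks ∈ [0.8, 1.6] for the shared orchid whole-genome duplication and
Ks < 0.2 for recent duplicates (both configurable; the defaults are chosen
so the canonical printed Ks values — 1.0658 and 1.4562 for the WGD pairs,
0.0433 and 0.0827 for the recent pairs — classify as expected).

The sliding-window scan (window 150 bp = 50 codons, step 9 bp = 3 codons,
in alignment coordinates) applies the same estimator per window; an
alignment shorter than one window yields a single flagged whole-length
window.  The test suite cross-checks the whole-pair estimator against
Biopython's independent NG86 implementation; Ka agrees to a few percent
while Ks differs by up to ~10 % because the two implementations treat
mutations-to-stop site exclusion differently (bbxkit renormalizes so sites
always sum to 3 per codon).

## Phylogeny and domain trajectory

Distances are Poisson-corrected mismatch fractions over shared non-gap
columns (p-distance available).  Neighbor joining is the standard
Saitou–Nei agglomeration with Q-matrix and deterministic tie-breaking
(lexicographically smallest taxon pair), which makes it exactly consistent
on additive matrices — the oracle used in the tests.  Bootstrap supports
come from column resampling; supports are the percentage of replicates
containing each bipartition of the full-data tree.

The domain-architecture trajectory encodes each protein as three binary
characters — duplicated B-BOX1, presence of B-BOX2, presence of CCT — and
runs two-pass Fitch parsimony on a tree rooted on the clade-V side (the
single-B-BOX state is taken as ancestral, consistent with green-algal
outgroups; the outgroup is configurable).  Ambiguities resolve toward the
ancestral state at the root and toward the parent below.  Each parent→child
state flip is labeled: B-BOX2 gain = B-BOX duplication, B-BOX2 loss =
B-BOX2 deletion, CCT gain/loss, B-BOX1 duplication/loss.  On the
clade-shaped five-leaf tree the reconstruction needs exactly four events —
B-BOX duplication, CCT gain, B-BOX2 deletion, B-BOX1 duplication — the
canonical trajectory from a single-B-BOX ancestor.  On a full family tree
homoplasy can add events; the pipeline reports whatever the reconstruction
requires.

In the end-to-end pipeline the family tree is built from pairwise-alignment
Poisson distances (constructing a multiple alignment is out of scope), so
column-resampling bootstrap does not apply there; the bootstrap operates on
any supplied equal-length alignment.

## Promoters and cis-elements

Promoters are the 1500 bp immediately 5′ of the annotated translation start
(ATG) on the coding strand, truncated (and flagged) at scaffold edges.  The
motif library ships as a versioned TSV of literal/IUPAC consensus strings
for 23 named plant elements in three categories (development, hormone,
stress); the consensus strings are compiled from the standard plant
promoter-element literature and are deliberately simple — the package's
claims are about the scanning and aggregation machinery, not about
replicating any particular motif database's matrices.  Scanning counts all
(possibly overlapping) matches on one or both strands, case-insensitively;
in strict mode (default) an N in the promoter never matches.  Cohort
aggregation produces the gene × motif grid, per-category totals and
within-category shares (shares in a category sum to 1 whenever its total is
positive).  Note that a palindromic consensus (Box 4, ATTAAT) is its own
reverse complement, so both-strand scans count each occurrence twice.

## Expression

FPKM bins are left-closed at 1 / 6.8 / 17.5 / 44.7.  Tissue-pattern groups
formalize qualitative descriptions as: A if the median FPKM across the
eight tissues is ≥ 6.8; B if FPKM < 1 in at least 7 of 8 tissues; C
otherwise (all thresholds exposed).  Venn regions are exact exclusive
membership counts, limited to six sets for readability.

qRT-PCR relative expression is 2^−ΔΔCt with one reference gene and one
control sample: per replicate ΔCt = Ct_target − Ct_reference,
ΔΔCt = mean ΔCt(treated) − mean ΔCt(control), fold = 2^−ΔΔCt.  Efficiency
correction (Pfaffl) is not modeled.  Significance stars come from a
two-sided Welch t-test on the replicate ΔCt values (** p < 0.01,
* p < 0.05); with three biological replicates this is a deliberately simple
choice.  The control is shared across timepoints by default (per-timepoint
controls are a record-level choice).

## Synthetic data: what it emulates, and what it does not

The generator produces, from one seed, the full input set of a two-genome
BBX family study with the canonical cardinalities: 19 + 16 genes in five
clades (3/3/6/17/6), 13 ortholog and 2 + 2 paralog pairs, the exon-count
histogram {1:8, 2:10, 3:7, 4:6, 5:2, 7:2}, paralog Ks values planted at
1.4562/0.0827 (Do) and 1.0658/0.0433 (Pe), a 9/7/1 split of pairs over the
selection bins with a single positively selected pair, promoter motif
totals giving the TGACG-motif 29 % and ABRE 23 % (32 occurrences) of the
hormone category and 98 Skn-1 motifs, expression groups of 5/8/6 genes, and
a Ct table with planted inductions up to 1700-fold (Ct noise sd 0.2, three
replicates).

Design points worth knowing:

* **Exactness by rejection.**  Domain-internal spacer positions avoid all
  anchor residue classes; promoter backgrounds are scrubbed of every
  library motif on both strands and insertion junctions are repaired; every
  assembled sequence is re-scanned and rebuilt until detection equals the
  plant.  Recovery tests are therefore exact rather than statistical.
* **Divergence process.**  Pairs diverge by explicit substitution events
  applied uniformly over the currently available synonymous or
  nonsynonymous single-nucleotide changes, with event counts fixed at
  target × (NG86 sites of the ancestor), split between the lineages
  (one-sided for derived recent paralogs).  Within the family,
  nonsynonymous events spare the diagnostic anchor codons — the functional
  constraint real domains are under — and are reallocated over the rest of
  the gene so the whole-gene Ka target is preserved; this also reproduces
  the empirical pattern that domains show lower Ka/Ks than their flanks.
* **Estimator-aware study sizes.**  Gene lengths are chosen so each planted
  quantity is estimable: paralog lineages are long (~1100 codons) because
  near-saturated (Ks ≈ 1.5) and low-event (Ks ≈ 0.04) estimates are
  otherwise dominated by noise; relaxed-purifying ortholog pairs are
  mid-length (~450 codons) so their ratios sit stably inside the 0.3–1 bin;
  strong-purifying pairs can be short.  Protein sizes consequently span a
  wide range, as the real family's molecular weights (7.5–61.7 kDa) do,
  though the longest synthetic genes exceed the real family's range.
* **Linker composition.**  Inter-domain linkers draw from the full 20-letter
  alphabet: a reduced alphabet behaves like low-complexity sequence and
  inflates chance alignment scores between unrelated proteins, which is
  exactly the artifact real pipelines mask away.
* **What passing does not show.**  The generator has no indels within
  genes, no alternative isoforms, no UTR exons, no compositional bias, no
  rate heterogeneity along the sequence, and its promoter background is
  uniform-random DNA.  Recovery on these data demonstrates the machinery's
  correctness at its stated task — not that the thresholds would reproduce
  any specific annotation on real assemblies, where noise sources the
  generator omits (fragmented gene models, motif databases' position
  weights, mapping noise in FPKM) dominate.

## Problem sizes and runtime

The default test suite and the acceptance script run the family at full
configured size (35 genes), the Ks-recovery simulation at 1000 codons × 50
replicates per target, the window-localization check at 400 codons × 10
replicates, and the bootstrap demonstration at 100 replicates on four taxa;
everything completes in a few minutes on one CPU.

## Known limitations

* NG86 with JC correction is the classical counting estimator; it has the
  usual mild biases near saturation (the convexity of the correction
  inflates high-Ks point estimates by several percent) and no
  transition/transversion or codon-frequency modeling.
* The sliding-window maximum is a noisy localizer: a background window with
  few synonymous differences can occasionally out-rank the planted segment,
  so localization is validated as a high success rate, not a certainty.
* Clade I vs II assignment without a tree is a flagged default, not an
  inference.
* The NJ tree on the family uses pairwise-alignment distances, which are
  not column-consistent the way a multiple alignment is; supports are
  therefore not produced for that tree.
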