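"""Global protein alignment and reciprocal-best-hit homolog detection.

At gene-family scale (tens of proteins) orthologs can be called as
reciprocal best hits (RBH) between genomes under a global Needleman–Wunsch
score, and paralogs as within-genome reciprocal best hits that additionally
score higher than either member's best between-genome hit (the classic
in-paralog criterion: the two copies are closer to each other than to
anything in the other genome).  Markov-clustering pipelines add nothing at
this size.  Alignment is delegated to Biopython's ``PairwiseAligner``
(affine gaps, BLOSUM62 by default); identity is counted over the aligned
(both non-gap) columns, coverage is those columns over the shorter input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

from .core_io import SeqRecord

__all__ = ["AlignmentResult", "HomologPair", "align_global", "find_homologs"]

log = logging.getLogger(__name__)

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class AlignmentResult:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    identity: float  # identical residues / aligned (both non-gap) columns
    coverage: float  # aligned (both non-gap) columns / shorter input length


@dataclass(frozen=True)
class HomologPair:
    """An unordered homolog pair, stored with lexicographically sorted ids."""

    id_a: str
    id_b: str
    relation: str  # {"ortholog", "paralog"}
    genome_a: str
    genome_b: str

    def __post_init__(self) -> None:
        if (self.relation == "ortholog") != (self.genome_a != self.genome_b):
            raise ValueError("ortholog pairs must span two genomes, paralogs one")
        if self.id_a > self.id_b:
            id_a, id_b = self.id_b, self.id_a
            genome_a, genome_b = self.genome_b, self.genome_a
            object.__setattr__(self, "id_a", id_a)
            object.__setattr__(self, "id_b", id_b)
            object.__setattr__(self, "genome_a", genome_a)
            object.__setattr__(self, "genome_b", genome_b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = Align.substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _sanitize(seq: str) -> str:
    # non-standard residues score as X (matrix default column)
    return "".join(aa if aa in _STANDARD else "X" for aa in seq.upper())


def align_global(
    a: SeqRecord | str,
    b: SeqRecord | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal global alignment with affine gaps; deterministic tie-breaking
    (the aligner's first reported optimum is used)."""
    id_a, seq_a = (a.id, a.seq) if isinstance(a, SeqRecord) else ("a", a)
    id_b, seq_b = (b.id, b.seq) if isinstance(b, SeqRecord) else ("b", b)
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(_sanitize(seq_a), _sanitize(seq_b))
    best = alignments[0]
    gapped_a, gapped_b = str(best[0]), str(best[1])
    both = [(x, y) for x, y in zip(gapped_a, gapped_b) if x != "-" and y != "-"]
    matches = sum(1 for x, y in both if x == y)
    n_cols = len(both)
    identity = matches / n_cols if n_cols else 0.0
    coverage = n_cols / min(len(seq_a), len(seq_b))
    return AlignmentResult(id_a, id_b, gapped_a, gapped_b, float(best.score), identity, coverage)


def _best_hits(
    queries: list[SeqRecord],
    targets: list[SeqRecord],
    cache: dict,
    matrix: str,
    gap_open: float,
    gap_extend: float,
    exclude_self: bool,
) -> dict[str, tuple[str | None, float]]:
    """(best target, best score) per query; score ties reject the query."""
    best: dict[str, tuple[str | None, float]] = {}
    for q in queries:
        scored: list[tuple[float, str]] = []
        for t in targets:
            if exclude_self and t.id == q.id:
                continue
            key = tuple(sorted((q.id, t.id)))
            if key not in cache:
                cache[key] = align_global(q, t, matrix, gap_open, gap_extend)
            scored.append((cache[key].score, t.id))
        if not scored:
            best[q.id] = (None, -math.inf)
            continue
        scored.sort(key=lambda st: (-st[0], st[1]))
        if len(scored) > 1 and scored[0][0] == scored[1][0]:
            log.info("best-hit tie for %s (%s vs %s); rejected", q.id, scored[0][1], scored[1][1])
            best[q.id] = (None, scored[0][0])
        else:
            best[q.id] = (scored[0][1], scored[0][0])
    return best


def find_homologs(
    genome_a_proteins: list[SeqRecord],
    genome_b_proteins: list[SeqRecord],
    genome_a: str = "A",
    genome_b: str = "B",
    min_identity: float = 0.4,
    min_coverage: float = 0.5,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[list[HomologPair], dict[tuple[str, str], AlignmentResult]]:
    """Orthologs (between-genome RBH) and paralogs (within-genome RBH).

    Every reported pair passes both the identity and coverage thresholds.
    Returns the pair list plus the alignment cache keyed by sorted id pairs,
    so downstream codon-level analyses reuse the protein alignments.
    """
    cache: dict[tuple[str, str], AlignmentResult] = {}
    pairs: list[HomologPair] = []

    def passes(x: str, y: str) -> bool:
        aln = cache[tuple(sorted((x, y)))]
        return aln.identity >= min_identity and aln.coverage >= min_coverage

    kwargs = (matrix, gap_open, gap_extend)
    have_both = bool(genome_a_proteins) and bool(genome_b_proteins)
    ab = ba = {}
    if have_both:
        ab = _best_hits(genome_a_proteins, genome_b_proteins, cache, *kwargs, exclude_self=False)
        ba = _best_hits(genome_b_proteins, genome_a_proteins, cache, *kwargs, exclude_self=False)
        for a_id, (b_id, score) in ab.items():
            if (
                b_id is not None
                and ba.get(b_id, (None,))[0] == a_id
                and score > 0
                and passes(a_id, b_id)
            ):
                pairs.append(HomologPair(a_id, b_id, "ortholog", genome_a, genome_b))

    # best between-genome score per gene: a within-genome pair must beat it
    # (the classic "closer to each other than to anything in the other
    # genome" criterion), which keeps genes with clear orthologs from being
    # paired up with distant family members
    cross_best = {q: s for q, (_, s) in ab.items()}
    cross_best.update({q: s for q, (_, s) in ba.items()})

    for prots, gname in ((genome_a_proteins, genome_a), (genome_b_proteins, genome_b)):
        if len(prots) < 2:
            continue
        within = _best_hits(prots, prots, cache, *kwargs, exclude_self=True)
        seen: set[tuple[str, str]] = set()
        for x, (y, score) in within.items():
            if y is None or within.get(y, (None,))[0] != x:
                continue
            key = tuple(sorted((x, y)))
            if key in seen or score <= 0 or not passes(x, y):
                continue
            if have_both and not (
                score > cross_best.get(x, -math.inf)
                and score > cross_best.get(y, -math.inf)
            ):
                continue
            seen.add(key)
            pairs.append(HomologPair(key[0], key[1], "paralog", gname, gname))

    pairs.sort(key=lambda p: (p.relation, p.key))
    return pairs, cache
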