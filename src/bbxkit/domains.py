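"""B-BOX / CCT domain detection, architecture typing and protein statistics.

The B-BOX zinc finger is recognized here by its conserved Cys/His anchor
scaffold with family-typical spacer ranges, not by a profile HMM: at
gene-family scale an anchor pattern captures exactly the residues the domain
needs to coordinate its two Zn ions, and makes every match auditable.

Two B-BOX flavours are distinguished:

* BBOX1 — canonicalized anchor scaffold C, C, C, C/H, H, H with spacings
  ``C-x(9,10)-C-x(6,10)-C-x(2,3)-[CH]-x(3,4)-H-x(5,10)-H``
  (five conserved Cys of which four are absolute, plus the His pair).
* BBOX2 — ``C-x(2,4)-H-x(7,10)-C-x(1,4)-D-x(4,7)-C-x(2)-C-x(3,6)-H-x(2,5)-H``.

The CCT (CONSTANS/CO-like/TOC1) domain is a 42-residue consensus
``R-x5-R-Y-x-E-K-x3-R-x3-K-x2-R-Y-x2-R-K-x2-A-x2-R-x-R-x-K-G-R-F-x-K``
whose 19 anchors are matched at fixed offsets; real CCTs deviate from the
consensus, so a match requires at least 80% of the anchors (configurable)
rather than all of them.

Clade assignment follows the standard BBX subfamily rule table: two B-BOX
domains plus CCT -> clade I or II (separable only phylogenetically), one
B-BOX plus CCT -> III, two B-BOX without CCT -> IV, one B-BOX without
CCT -> V; proteins without any B-BOX domain are excluded from the family.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .core_io import SeqRecord

__all__ = [
    "DomainPattern",
    "DomainHit",
    "Architecture",
    "BBOX1",
    "BBOX2",
    "CCT",
    "DEFAULT_PATTERNS",
    "parse_pattern",
    "scan_domain",
    "scan_all",
    "resolve_overlaps",
    "assign_architecture",
    "classify_clade",
    "compute_mw",
    "compute_pi",
    "net_charge",
]

CLADES = ("I", "II", "III", "IV", "V", "unclassified")


@dataclass(frozen=True)
class DomainPattern:
    """An anchor-residue pattern: residue classes with inter-anchor gap ranges.

    ``anchors[i]`` is the set of residues allowed at anchor *i*;
    ``gaps[i]`` is the (min, max) number of unconstrained residues between
    anchors *i* and *i+1*.  ``min_anchor_fraction`` < 1 allows degenerate
    matches (used for the long CCT consensus) and is only supported for
    fixed-spacing patterns.
    """

    name: str
    anchors: tuple[frozenset, ...]
    gaps: tuple[tuple[int, int], ...]
    min_anchor_fraction: float = 1.0

    def __post_init__(self) -> None:
        if len(self.gaps) != len(self.anchors) - 1:
            raise ValueError(f"{self.name}: need one gap range between each anchor pair")
        for lo, hi in self.gaps:
            if lo < 0 or hi < lo:
                raise ValueError(f"{self.name}: bad gap range ({lo},{hi})")
        if self.name.startswith("BBOX") and len(self.anchors) < 4:
            raise ValueError(f"{self.name}: B-BOX patterns need >=4 anchor residues")

    @property
    def fixed_spacing(self) -> bool:
        return all(lo == hi for lo, hi in self.gaps)

    @property
    def max_span(self) -> int:
        return len(self.anchors) + sum(hi for _, hi in self.gaps)

    @property
    def min_span(self) -> int:
        return len(self.anchors) + sum(lo for lo, _ in self.gaps)


@dataclass
class DomainHit:
    protein_id: str
    domain: str
    start: int  # 0-based half-open residue coordinates
    end: int
    matched_anchors: int

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Architecture:
    protein_id: str
    code: tuple[str, ...]  # domain labels N->C, e.g. ("B1", "B2", "CCT")
    clade: str = "unclassified"
    architecture_only: bool = False  # clade I/II resolved without a tree
    atypical: bool = False  # e.g. CCT N-terminal to every B-BOX


_PATTERN_RE = re.compile(r"\[([A-Z]+)\]|x\((\d+)(?:,(\d+))?\)|([A-Z])")


def parse_pattern(name: str, text: str, min_anchor_fraction: float = 1.0) -> DomainPattern:
    """Parse ``C-x(2,4)-H-...`` / ``[CH]`` pattern notation."""
    anchors: list[frozenset] = []
    gaps: list[tuple[int, int]] = []
    pending_gap = 0, 0
    first = True
    for tok in text.split("-"):
        m = _PATTERN_RE.fullmatch(tok.strip())
        if not m:
            raise ValueError(f"{name}: cannot parse token {tok!r}")
        cls, lo, hi, single = m.groups()
        if lo is not None:
            lo_i = int(lo)
            hi_i = int(hi) if hi is not None else lo_i
            pending_gap = (pending_gap[0] + lo_i, pending_gap[1] + hi_i)
            continue
        residues = frozenset(cls if cls else single)
        if not first:
            gaps.append(pending_gap)
        anchors.append(residues)
        pending_gap = (0, 0)
        first = False
    return DomainPattern(name, tuple(anchors), tuple(gaps), min_anchor_fraction)


BBOX1 = parse_pattern("BBOX1", "C-x(9,10)-C-x(6,10)-C-x(2,3)-[CH]-x(3,4)-H-x(5,10)-H")
BBOX2 = parse_pattern("BBOX2", "C-x(2,4)-H-x(7,10)-C-x(1,4)-D-x(4,7)-C-x(2)-C-x(3,6)-H-x(2,5)-H")
CCT = parse_pattern(
    "CCT",
    "R-x(5)-R-Y-x(1)-E-K-x(3)-R-x(3)-K-x(2)-R-Y-x(2)-R-K-x(2)-A-x(2)-R-x(1)-R-x(1)-K-G-R-F-x(1)-K",
    min_anchor_fraction=0.8,
)

DEFAULT_PATTERNS = (BBOX1, BBOX2, CCT)


def _match_at(seq: str, pattern: DomainPattern, start: int) -> int | None:
    """Longest full-anchor match beginning exactly at ``start``; None if none.

    Depth-first over gap choices, larger gaps first, so the first hit found
    is the longest — the deterministic tie-break the scanner promises.
    """

    def rec(anchor_idx: int, pos: int) -> int | None:
        if pos >= len(seq) or seq[pos] not in pattern.anchors[anchor_idx]:
            return None
        if anchor_idx == len(pattern.anchors) - 1:
            return pos + 1
        lo, hi = pattern.gaps[anchor_idx]
        for gap in range(hi, lo - 1, -1):
            end = rec(anchor_idx + 1, pos + 1 + gap)
            if end is not None:
                return end
        return None

    return rec(0, start)


def _scan_fixed(seq: str, pattern: DomainPattern) -> list[tuple[int, int, int]]:
    """Sliding-window scan for fixed-spacing patterns with partial anchors."""
    offsets = [0]
    for lo, _ in pattern.gaps:
        offsets.append(offsets[-1] + 1 + lo)
    span = offsets[-1] + 1
    needed = math.ceil(pattern.min_anchor_fraction * len(pattern.anchors) - 1e-9)
    out = []
    for start in range(0, len(seq) - span + 1):
        matched = sum(
            1
            for off, cls in zip(offsets, pattern.anchors)
            if seq[start + off] in cls
        )
        if matched >= needed:
            out.append((start, start + span, matched))
    return out


def scan_domain(protein: SeqRecord, pattern: DomainPattern) -> list[DomainHit]:
    """All maximal non-overlapping matches of ``pattern``, scanned N->C.

    Overlaps are resolved greedily left-to-right: the earliest start wins,
    and at equal starts the longest match wins.
    """
    seq = protein.seq.upper()
    raw: list[tuple[int, int, int]] = []
    if pattern.fixed_spacing and pattern.min_anchor_fraction < 1.0:
        raw = _scan_fixed(seq, pattern)
    else:
        for start in range(len(seq)):
            end = _match_at(seq, pattern, start)
            if end is not None:
                raw.append((start, end, len(pattern.anchors)))
    hits: list[DomainHit] = []
    cursor = -1
    for start, end, matched in raw:  # already sorted by (start, -length) per scan order
        if start <= cursor:
            continue
        hits.append(DomainHit(protein.id, pattern.name, start, end, matched))
        cursor = end - 1
    return hits


def resolve_overlaps(hits: list[DomainHit]) -> list[DomainHit]:
    """Greedy cross-pattern overlap resolution: earliest start, then longest."""
    ordered = sorted(hits, key=lambda h: (h.start, -(h.end - h.start), h.domain))
    resolved: list[DomainHit] = []
    for hit in ordered:
        if any(hit.overlaps(kept) for kept in resolved):
            continue
        resolved.append(hit)
    return resolved


def scan_all(
    protein: SeqRecord, patterns: tuple[DomainPattern, ...] = DEFAULT_PATTERNS
) -> list[DomainHit]:
    """Scan with every pattern and resolve overlaps across patterns."""
    hits: list[DomainHit] = []
    for pattern in patterns:
        hits.extend(scan_domain(protein, pattern))
    return resolve_overlaps(hits)


_DOMAIN_LABEL = {"BBOX1": "B1", "BBOX2": "B2", "CCT": "CCT"}


def assign_architecture(protein_id: str, hits: list[DomainHit]) -> Architecture:
    """Map resolved domain hits to an N->C architecture code and clade bucket.

    Proteins with zero B-BOX hits stay ``unclassified`` (excluded from the
    family); a CCT N-terminal to every B-BOX is biologically atypical and is
    flagged rather than force-fitted into a clade.
    """
    ordered = sorted(hits, key=lambda h: h.start)
    code = tuple(_DOMAIN_LABEL.get(h.domain, h.domain) for h in ordered)
    n_bbox = sum(1 for label in code if label in {"B1", "B2"})
    has_cct = "CCT" in code
    arch = Architecture(protein_id=protein_id, code=code)
    if n_bbox == 0:
        return arch
    if has_cct:
        first_cct = code.index("CCT")
        first_bbox = min(i for i, label in enumerate(code) if label in {"B1", "B2"})
        if first_cct < first_bbox:
            arch.atypical = True
            return arch
    if n_bbox >= 2 and has_cct:
        arch.clade = "I/II"
    elif n_bbox == 1 and has_cct:
        arch.clade = "III"
    elif n_bbox >= 2:
        arch.clade = "IV"
    else:
        arch.clade = "V"
    return arch


def classify_clade(arch: Architecture, tree_placement: str | None = None) -> str:
    """Resolve the clade, including the I-vs-II double-B-BOX+CCT ambiguity.

    Architecture alone cannot separate clades I and II (they differ by B-BOX2
    sequence divergence, a phylogenetic signal); with no placement supplied
    the protein defaults to II and is flagged ``architecture_only``.
    """
    if arch.clade == "I/II":
        if tree_placement in {"I", "II"}:
            arch.clade = tree_placement
        else:
            arch.clade = "II"
            arch.architecture_only = True
    elif tree_placement and arch.clade == "unclassified" and not arch.atypical:
        arch.clade = tree_placement
    return arch.clade


# --- physicochemical statistics (ExPASy conventions) -----------------------

# Average (isotope-weighted) residue masses, Da
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER = 18.01524

# Bjellqvist pKa set (the ExPASy default): side chains plus termini, with the
# residue-specific terminal adjustments.
_PKA_POSITIVE = {"K": 10.0, "R": 12.0, "H": 5.98}
_PKA_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_PKA_CTERM_DEFAULT = 3.55
_PKA_CTERM = {"D": 4.55, "E": 4.75}
_PKA_NTERM_DEFAULT = 7.5
_PKA_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}


def _check_sequence(protein: str) -> str:
    seq = protein.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    bad = [i for i, aa in enumerate(seq) if aa not in _RESIDUE_MASS]
    if bad:
        shown = ", ".join(f"{seq[i]}@{i}" for i in bad[:10])
        raise ValueError(f"ambiguous/non-standard residues: {shown}")
    return seq


def compute_mw(protein: str | SeqRecord) -> float:
    """Average molecular weight in daltons: residue masses plus one water."""
    seq = _check_sequence(protein.seq if isinstance(protein, SeqRecord) else protein)
    return sum(_RESIDUE_MASS[aa] for aa in seq) + _WATER


def net_charge(protein: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge of the protein at the given pH."""
    seq = _check_sequence(protein)
    nterm_pka = _PKA_NTERM.get(seq[0], _PKA_NTERM_DEFAULT)
    cterm_pka = _PKA_CTERM.get(seq[-1], _PKA_CTERM_DEFAULT)
    charge = 1.0 / (1.0 + 10 ** (ph - nterm_pka))
    charge -= 1.0 / (1.0 + 10 ** (cterm_pka - ph))
    for aa in seq:
        if aa in _PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10 ** (ph - _PKA_POSITIVE[aa]))
        elif aa in _PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (_PKA_NEGATIVE[aa] - ph))
    return charge


def compute_pi(protein: str | SeqRecord, tol: float = 1e-4) -> float:
    """Isoelectric point: pH of zero net charge, by bisection on [0, 14].

    Net charge is monotone decreasing in pH, and the termini always ionize,
    so a unique root exists for every sequence.
    """
    seq = protein.seq if isinstance(protein, SeqRecord) else protein
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return round(0.5 * (lo + hi), 2)
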