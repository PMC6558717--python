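"""Seeded synthetic-data generators with recorded ground truth.

Every input the analysis pipeline consumes can be generated here at toy
scale, shaped like a two-orchid BBX family study: two genomes carrying 19
and 16 family genes, 13 ortholog + 2+2 paralog pairs, clade architectures
planted from the canonical domain patterns, 1500 bp promoters with exact
planted cis-element counts, an 8-tissue FPKM matrix with a 5/8/6 group
structure, and a Ct table with planted fold changes (including one
extreme ~1700-fold induction).

Design notes:

* Backgrounds are rejection-sampled so planted signals are the only
  signals: domain-internal spacer positions avoid every anchor residue
  class, promoter backgrounds are scrubbed of all library motifs on both
  strands, and each assembled sequence is re-scanned and rebuilt until
  detection equals the plant.  Recovery tests are therefore exact, not
  statistical.
* Coding-sequence pairs diverge by an explicit substitution process whose
  synonymous and nonsynonymous event counts are tuned so the expected
  NG86 estimates equal the requested Ka/Ks targets.  Within the family,
  nonsynonymous events spare the diagnostic domain-anchor codons —
  the functional constraint real domains are under — but are reallocated
  over the rest of the gene so the whole-gene Ka target is preserved.
* All randomness flows from one integer seed; identical seeds give
  byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import GeneModel, Promoter, SeqRecord, translate_cds
from .cis_elements import MotifDefinition, load_motif_library, scan_promoter
from .domains import (
    BBOX1,
    BBOX2,
    CCT,
    DEFAULT_PATTERNS,
    DomainPattern,
    assign_architecture,
    scan_all,
)
from .evolution import GENETIC_CODE, STOP_CODONS, ng86_sites

__all__ = [
    "SimulationConfig",
    "FamilyData",
    "PairSpec",
    "DEFAULT_PAIR_PLAN",
    "make_family",
    "evolve_pair",
    "evolve_chimeric_pair",
    "make_promoters",
    "make_fpkm",
    "make_qpcr",
    "build_clade_protein",
    "reverse_translate",
]

# Domain X-position alphabet: excludes every anchor residue class of the
# three domain patterns (C,H,D for the B-BOXes; R,Y,E,K,A,G,F for CCT) so
# anchors inside a planted domain occur only at the planted offsets.
SAFE_AA = "ILMNPQSTVW"
# Linkers use the full standard alphabet (realistic composition; a reduced
# alphabet behaves like low-complexity sequence and inflates chance
# alignment between unrelated proteins).  Accidental domain matches in
# linkers are vanishingly rare and caught by the rejection re-scan.
FULL_AA = "ACDEFGHIKLMNPQRSTVWY"

_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(GENETIC_CODE.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)

TREATMENTS = ("ABA", "SA", "AgNO3", "MeJA")
TIMEPOINTS = (24, 48, 72, 96)


@dataclass(frozen=True)
class PairSpec:
    """One planted lineage: a homolog pair, or a singleton gene."""

    gene_a: str
    genome_a: str
    gene_b: str | None = None  # None -> singleton
    genome_b: str | None = None
    ks: float = 0.0
    ka: float = 0.0
    clade: str = "IV"
    long_gene: bool = False  # extra linker length (size diversity)
    linker: tuple[int, int] | None = None  # explicit main-linker range (aa)
    derive_b_from: str | None = None  # one-sided divergence from this gene id

    @property
    def relation(self) -> str | None:
        if self.gene_b is None:
            return None
        return "ortholog" if self.genome_a != self.genome_b else "paralog"


# The default family plan mirrors the cardinalities of a two-orchid BBX
# study: 19 + 16 genes, 13 orthologs, two paralog pairs per genome (one
# WGD-age with Ks near 1-1.5, one recent), nine pairs with Ka/Ks < 0.3,
# seven in 0.3-1, and a single pair under positive selection.
DEFAULT_PAIR_PLAN: tuple[PairSpec, ...] = (
    PairSpec("DoBBX01", "Do", "PeBBX02", "Pe", ks=0.6, ka=0.6 * 0.12, clade="IV"),
    PairSpec("DoBBX02", "Do", "PeBBX03", "Pe", ks=0.8, ka=0.8 * 0.15, clade="IV"),
    PairSpec("DoBBX03", "Do", "PeBBX04", "Pe", ks=1.0, ka=1.0 * 0.10, clade="IV"),
    PairSpec("DoBBX04", "Do", "PeBBX05", "Pe", ks=0.5, ka=0.5 * 0.18, clade="IV"),
    PairSpec("DoBBX06", "Do", "PeBBX06", "Pe", ks=0.9, ka=0.9 * 0.12, clade="V"),
    PairSpec("DoBBX08", "Do", "PeBBX09", "Pe", ks=0.7, ka=0.7 * 0.20, clade="III",
             linker=(300, 400)),
    PairSpec("DoBBX09", "Do", "PeBBX10", "Pe", ks=1.2, ka=1.2 * 0.10, clade="III"),
    # relaxed-purifying pairs: Ka capped near 0.3 so protein identity stays
    # comfortably above the homolog-detection thresholds, and mid-length
    # genes so the mid-bin ratio estimates sit stably inside 0.3-1
    PairSpec("DoBBX12", "Do", "PeBBX11", "Pe", ks=0.6, ka=0.6 * 0.50, clade="II",
             linker=(300, 400)),
    PairSpec("DoBBX13", "Do", "PeBBX12", "Pe", ks=0.5, ka=0.5 * 0.55, clade="I",
             linker=(300, 400)),
    PairSpec("DoBBX14", "Do", "PeBBX13", "Pe", ks=0.6, ka=0.6 * 0.45, clade="V",
             linker=(300, 400)),
    PairSpec("DoBBX15", "Do", "PeBBX15", "Pe", ks=0.5, ka=0.5 * 0.60, clade="V",
             linker=(300, 400)),
    PairSpec("DoBBX16", "Do", "PeBBX16", "Pe", ks=0.6, ka=0.6 * 0.50, clade="IV",
             linker=(300, 400)),
    # the single positively selected pair (kept alignable: Ka/Ks = 1.5 at
    # moderate divergence, not an extreme Ka that would erase homology signal)
    # long lineage: PeBBX08 also seeds the recent Pe paralog below, which
    # needs a long gene for a stable low-Ks estimate
    PairSpec("DoBBX05", "Do", "PeBBX08", "Pe", ks=0.2, ka=0.2 * 1.50, clade="IV",
             linker=(900, 1000)),
    # paralogs: WGD-age and recent, one per genome.  These lineages are long
    # (~1100 codons): the WGD pairs' high synonymous divergence then stays
    # clear of JC saturation, and the recent pairs' few substitution events
    # still support a stable Ka/Ks point estimate.
    PairSpec("DoBBX07", "Do", "DoBBX18", "Do", ks=1.4562, ka=1.4562 * 0.15, clade="IV",
             linker=(900, 1000)),
    PairSpec("DoBBX10", "Do", "DoBBX11", "Do", ks=0.0827, ka=0.0827 * 0.55, clade="III",
             linker=(900, 1000)),
    PairSpec("PeBBX01", "Pe", "PeBBX07", "Pe", ks=1.0658, ka=1.0658 * 0.15, clade="IV",
             linker=(900, 1000)),
    # recent Pe paralog: PeBBX14 diverges one-sidedly from PeBBX08, which is
    # itself an ortholog-pair member (so 13 + 2 + 2 pairs fit in 19 + 16 genes)
    PairSpec("PeBBX08", "Pe", "PeBBX14", "Pe", ks=0.0433, ka=0.0433 * 0.55, clade="IV",
             derive_b_from="PeBBX08"),  # length inherited from PeBBX08
    # singletons, deliberately of very different sizes (the family's printed
    # molecular weights span 7.5-61.7 kDa)
    PairSpec("DoBBX17", "Do", clade="II"),
    PairSpec("DoBBX19", "Do", clade="I", long_gene=True),
)

# family exon-count histogram planted over the 35 genes
DEFAULT_EXON_HISTOGRAM = {7: 2, 5: 2, 4: 6, 3: 7, 2: 10, 1: 8}

# cis-element totals planted across the cohort, in scan units (both strands;
# palindromic motifs count twice per physical insertion).  TGACG-motif is 29%
# and ABRE 23% (32 occurrences) of the hormone category; Skn-1-motif
# dominates the development category.
DEFAULT_MOTIF_TOTALS = {
    "Skn-1-motif": 98, "GCN4_motif": 20, "CAT-box": 15, "CCGTCC-box": 12,
    "O2-site": 8, "MRE": 14, "Box 4": 24, "circadian": 10,
    "TGACG-motif": 40, "ABRE": 32, "TGA-element": 12, "AuxRR-core": 8,
    "GARE-motif": 10, "P-box": 9, "TATC-box": 10, "ERE": 18,
    "ARE": 30, "Box-W1": 10, "HSE": 15, "TC-rich repeats": 12,
    "GC-motif": 8, "MBS": 20, "LTR": 14,
}

DEFAULT_QPCR_FOLDS = {
    ("DoBBX17", "ABA", 96): 1700.0,
    ("DoBBX11", "ABA", 96): 100.0,
    ("DoBBX17", "SA", 96): 20.0,
    ("DoBBX17", "MeJA", 48): 65.0,
    ("DoBBX16", "MeJA", 24): 10.0,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    pair_plan: tuple[PairSpec, ...] = DEFAULT_PAIR_PLAN
    exon_histogram: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_EXON_HISTOGRAM)
    )
    promoter_length: int = 1500
    motif_totals: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_TOTALS)
    )
    fpkm_group_sizes: tuple[int, int, int] = (5, 8, 6)  # A, B, C over the Do genes
    qpcr_folds: dict[tuple[str, str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_QPCR_FOLDS)
    )
    ct_noise_sd: float = 0.2
    n_replicates: int = 3

    def validate(self) -> None:
        genes = [s.gene_a for s in self.pair_plan] + [
            s.gene_b for s in self.pair_plan if s.gene_b
        ]
        shared = {s.derive_b_from for s in self.pair_plan if s.derive_b_from}
        dupes = {g for g in genes if genes.count(g) > 1} - shared
        if dupes:
            raise ValueError(f"gene ids used twice in the pair plan: {sorted(dupes)}")
        if sum(self.exon_histogram.values()) != len(set(genes)):
            raise ValueError("exon histogram must cover every planted gene exactly once")
        if sum(self.fpkm_group_sizes) != sum(
            1 for g in set(genes) if g.startswith("Do")
        ):
            raise ValueError("FPKM group sizes must sum to the Do gene count")


@dataclass
class FamilyData:
    genomes: dict[str, list[SeqRecord]]
    gff3: dict[str, str]
    proteins: dict[str, list[SeqRecord]]
    cds: dict[str, list[SeqRecord]]
    models: dict[str, list[GeneModel]]
    promoters: dict[str, Promoter]
    truth: dict


# --- protein construction ---------------------------------------------------


def _instantiate_pattern(rng: np.random.Generator, pattern: DomainPattern) -> tuple[str, list[int]]:
    """A concrete domain instance plus the (domain-local) anchor positions."""
    while True:
        gaps = [int(rng.integers(lo, hi + 1)) for lo, hi in pattern.gaps]
        if pattern.name == "BBOX2" and gaps[0] + gaps[1] < 10:
            # would let the first three Cys/His anchors double as a BBOX1 prefix
            continue
        break
    out: list[str] = []
    anchor_pos: list[int] = []
    for idx, residues in enumerate(pattern.anchors):
        anchor_pos.append(len(out))
        out.append(sorted(residues)[int(rng.integers(len(residues)))])
        if idx < len(gaps):
            out.extend(rng.choice(list(SAFE_AA), size=gaps[idx]))
    return "".join(out), anchor_pos


_CLADE_DOMAINS = {
    "I": ("BBOX1", "BBOX1", "CCT"),
    "II": ("BBOX1", "BBOX2", "CCT"),
    "III": ("BBOX1", "CCT"),
    "IV": ("BBOX1", "BBOX2"),
    "V": ("BBOX1",),
}
_PATTERN_BY_NAME = {"BBOX1": BBOX1, "BBOX2": BBOX2, "CCT": CCT}


def build_clade_protein(
    rng: np.random.Generator,
    clade: str,
    long_gene: bool = False,
    linker_range: tuple[int, int] | None = None,
    max_attempts: int = 50,
) -> tuple[str, list[tuple[str, int, int]], list[int]]:
    """A protein realizing the clade's domain architecture.

    Returns (sequence, planted domains as (name, start, end), anchor residue
    positions).  The assembled protein is re-scanned and rebuilt until the
    scan recovers exactly the planted architecture — rejection sampling
    against accidental cross-pattern matches.
    """
    if clade not in _CLADE_DOMAINS:
        raise ValueError(f"unknown clade {clade!r}")
    layout = _CLADE_DOMAINS[clade]
    for _ in range(max_attempts):
        parts: list[str] = []
        domains: list[tuple[str, int, int]] = []
        anchors: list[int] = []

        def linker(lo: int, hi: int) -> None:
            parts.append("".join(rng.choice(list(FULL_AA), size=int(rng.integers(lo, hi + 1)))))

        linker(10, 30)
        for i, name in enumerate(layout):
            if i > 0:
                if name == "CCT":
                    # CCT sits near the C terminus, far from the B-BOX block;
                    # long genes span a wide size range, like the real family
                    main = linker_range or ((200, 640) if long_gene else (60, 120))
                    linker(*main)
                else:
                    linker(5, 15)
            start = sum(len(p) for p in parts)
            seq, local_anchors = _instantiate_pattern(rng, _PATTERN_BY_NAME[name])
            parts.append(seq)
            domains.append((name, start, start + len(seq)))
            anchors.extend(start + a for a in local_anchors)
        if "CCT" not in layout:
            # architectures without CCT still carry a substantial
            # C-terminal region, like the real family members
            main = linker_range or ((200, 640) if long_gene else (60, 120))
            linker(*main)
        linker(15, 40)
        protein = "".join(parts)
        hits = scan_all(SeqRecord("candidate", protein, "protein"))
        planted = [(n, s, e) for n, s, e in domains]
        found = [(h.domain, h.start, h.end) for h in hits]
        if found == planted:
            return protein, domains, anchors
    raise RuntimeError(f"could not build a clean clade-{clade} protein")


def reverse_translate(rng: np.random.Generator, protein: str) -> str:
    """Random synonymous codon choice; never emits a stop codon."""
    return "".join(
        _CODONS_FOR[aa][int(rng.integers(len(_CODONS_FOR[aa])))] for aa in protein
    )


# --- divergence simulation --------------------------------------------------


def _codon_options(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            if (GENETIC_CODE[mut] == aa) == synonymous:
                out.append((pos, nt))
    return out


def _apply_events(
    rng: np.random.Generator,
    codons: list[str],
    n_syn: int,
    n_nonsyn: int,
    nonsyn_allowed: np.ndarray,
) -> tuple[list[str], int, int]:
    """Apply substitution events one at a time, uniformly over the currently
    available mutations of the requested kind."""
    codons = list(codons)
    syn_w = np.array([len(_codon_options(c, True)) for c in codons], dtype=float)
    non_w = np.array(
        [len(_codon_options(c, False)) for c in codons], dtype=float
    ) * nonsyn_allowed
    kinds = ["s"] * n_syn + ["n"] * n_nonsyn
    rng.shuffle(kinds)
    applied_s = applied_n = 0
    for kind in kinds:
        weights = syn_w if kind == "s" else non_w
        total = weights.sum()
        if total <= 0:
            continue  # nothing mutable of this kind (degenerate tiny inputs)
        idx = int(rng.choice(len(codons), p=weights / total))
        options = _codon_options(codons[idx], kind == "s")
        pos, nt = options[int(rng.integers(len(options)))]
        codons[idx] = codons[idx][:pos] + nt + codons[idx][pos + 1 :]
        syn_w[idx] = len(_codon_options(codons[idx], True))
        non_w[idx] = len(_codon_options(codons[idx], False)) * nonsyn_allowed[idx]
        if kind == "s":
            applied_s += 1
        else:
            applied_n += 1
    return codons, applied_s, applied_n


def evolve_pair(
    ancestral_cds: str,
    target_ks: float,
    target_ka: float,
    rng: np.random.Generator,
    protected_codons: frozenset = frozenset(),
    split: tuple[float, float] = (0.5, 0.5),
) -> tuple[str, str, dict]:
    """Evolve two descendants of a stop-free CDS to target NG86 divergences.

    Synonymous/nonsynonymous event counts are Poisson with means
    ``target * sites(ancestor)``, split between the two lineages
    (``split=(0,1)`` gives one-sided divergence, e.g. a derived recent
    paralog).  ``protected_codons`` are exempt from nonsynonymous change;
    their nonsynonymous-site mass is reallocated to the rest of the gene so
    the whole-gene Ka target is preserved.
    """
    if target_ks < 0 or target_ka < 0:
        raise ValueError("divergence targets must be non-negative")
    if target_ks > 3 or target_ka > 3:
        raise ValueError("targets beyond saturation (> 3) are not simulable")
    if len(ancestral_cds) % 3:
        raise ValueError("ancestral CDS length must be a multiple of 3")
    codons = [ancestral_cds[i : i + 3].upper() for i in range(0, len(ancestral_cds), 3)]
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("ancestral CDS must be stop-free")
    if not math.isclose(sum(split), 1.0):
        raise ValueError("lineage split must sum to 1")

    # event counts fixed at their expectation (the tuning that makes the
    # expected NG86 estimate equal the target); placement remains random
    s_sites = sum(ng86_sites(c)[0] for c in codons)
    n_sites = sum(ng86_sites(c)[1] for c in codons)
    n_syn = int(round(target_ks * s_sites))
    n_non = int(round(target_ka * n_sites))
    syn_a = int(rng.binomial(n_syn, split[0])) if n_syn else 0
    non_a = int(rng.binomial(n_non, split[0])) if n_non else 0
    allowed = np.array(
        [0.0 if i in protected_codons else 1.0 for i in range(len(codons))]
    )
    cds_a, sa, na = _apply_events(rng, codons, syn_a, non_a, allowed)
    cds_b, sb, nb = _apply_events(rng, codons, n_syn - syn_a, n_non - non_a, allowed)
    truth = {
        "target_ks": target_ks,
        "target_ka": target_ka,
        "syn_events": sa + sb,
        "nonsyn_events": na + nb,
        "s_sites_ancestor": s_sites,
        "n_sites_ancestor": n_sites,
    }
    return "".join(cds_a), "".join(cds_b), truth


def evolve_chimeric_pair(
    ancestral_cds: str,
    target_ks: float,
    background_ka: float,
    window_start_codon: int,
    window_codons: int,
    window_ka: float,
    rng: np.random.Generator,
) -> tuple[str, str, dict]:
    """A pair with homogeneous Ks but elevated Ka inside one segment —
    the planted-positive-selection fixture for window-scan tests."""
    n_codons = len(ancestral_cds) // 3
    window = frozenset(range(window_start_codon, window_start_codon + window_codons))
    if max(window, default=0) >= n_codons:
        raise ValueError("selection window extends past the CDS")
    outside = frozenset(range(n_codons)) - window
    cds_a, cds_b, truth = evolve_pair(
        ancestral_cds, target_ks, background_ka, rng, protected_codons=window
    )
    # extra nonsynonymous events confined to the window
    codons_a = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)]
    window_n_sites = sum(ng86_sites(ancestral_cds[3 * i : 3 * i + 3])[1] for i in window)
    n_extra = int(round(window_ka * window_n_sites))
    allowed = np.array([1.0 if i in window else 0.0 for i in range(n_codons)])
    extra_a = int(rng.binomial(n_extra, 0.5)) if n_extra else 0
    codons_a, _, ea = _apply_events(rng, codons_a, 0, extra_a, allowed)
    codons_b, _, eb = _apply_events(rng, codons_b, 0, n_extra - extra_a, allowed)
    truth.update(
        window_start_bp=3 * window_start_codon,
        window_end_bp=3 * (window_start_codon + window_codons),
        window_ka=window_ka,
        window_nonsyn_events=ea + eb,
    )
    return "".join(codons_a), "".join(codons_b), truth


# --- promoters --------------------------------------------------------------


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(seq))


def _scrub_background(
    rng: np.random.Generator, length: int, library: list[MotifDefinition]
) -> str:
    """Uniform-random DNA with every library motif scrubbed out (both strands)."""
    from .cis_elements import _motif_regex

    seq = list(rng.choice(list("ACGT"), size=length))
    patterns = [(_motif_regex(m.consensus), len(m.consensus)) for m in library]
    for _ in range(200):
        text = "".join(seq)
        dirty = False
        for pattern, width in patterns:
            for match in pattern.finditer(text):
                dirty = True
                start = match.start()
                for k in range(start, start + width):
                    seq[k] = str(rng.choice(list("ACGT")))
            rc = _revcomp(text)
            for match in pattern.finditer(rc):
                dirty = True
                start = length - match.start() - width
                for k in range(start, start + width):
                    seq[k] = str(rng.choice(list("ACGT")))
        if not dirty:
            return "".join(seq)
    raise RuntimeError("could not scrub promoter background of motif matches")


def _instantiate_motif(rng: np.random.Generator, motif: MotifDefinition,
                       library: list[MotifDefinition]) -> str:
    """Concrete instance of a consensus; ambiguous positions are filled so the
    instance contains no other library motif on either strand."""
    from .cis_elements import _IUPAC, count_matches

    is_palindromic = motif.consensus == _revcomp_iupac(motif.consensus)
    for _ in range(200):
        inst = "".join(
            _IUPAC[sym][int(rng.integers(len(_IUPAC[sym])))]
            for sym in motif.consensus.upper()
        )
        expected = {m.name: 0 for m in library}
        expected[motif.name] = 2 if is_palindromic else 1
        actual = {
            m.name: count_matches(inst, m.consensus, strands="both") for m in library
        }
        if actual == expected:
            return inst
    raise RuntimeError(f"could not instantiate motif {motif.name} cleanly")


def _revcomp_iupac(consensus: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
            "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
            "N": "N"}
    return "".join(comp[c] for c in reversed(consensus.upper()))


def _repair_junctions(
    rng: np.random.Generator,
    seq: list[str],
    slots: list[tuple[int, int]],
    library: list[MotifDefinition],
    expected: dict[str, int],
) -> list[str] | None:
    """Scrub spurious motif matches created at insertion junctions.

    Planted instances are internally clean, so any unexpected match must
    include at least one background base; those bases are re-randomized
    until the scan matches the plan exactly.  Returns None if repair fails
    (caller rebuilds the promoter from scratch).
    """
    from .cis_elements import _motif_regex

    in_slot = [False] * len(seq)
    for s, e in slots:
        for i in range(s, e):
            in_slot[i] = True
    length = len(seq)
    for _ in range(60):
        dirty = False
        for motif in library:
            pattern = _motif_regex(motif.consensus)
            width = len(motif.consensus)
            text = "".join(seq)
            spans = [(m.start(), m.start() + width) for m in pattern.finditer(text)]
            rc = _revcomp(text)
            spans += [
                (length - m.start() - width, length - m.start())
                for m in pattern.finditer(rc)
            ]
            if len(spans) <= expected.get(motif.name, 0):
                continue
            for s, e in spans:
                bg = [i for i in range(s, e) if not in_slot[i]]
                if not bg:
                    continue  # a planted instance; leave it alone
                dirty = True
                for i in bg:
                    seq[i] = str(rng.choice(list("ACGT")))
        if not dirty:
            return seq
    return None


def make_promoters(
    config: SimulationConfig,
    gene_ids: list[str],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, Promoter], dict]:
    """Promoters with exact planted motif counts (in both-strand scan units).

    Counts are distributed over genes multinomially, instances are inserted
    at non-overlapping positions on either strand, and each promoter is
    verified by re-scanning; palindromic motifs count twice per insertion.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    library = load_motif_library()
    by_name = {m.name: m for m in library}
    unknown = set(config.motif_totals) - set(by_name)
    if unknown:
        raise ValueError(f"motif totals reference unknown motifs: {sorted(unknown)}")

    # physical insertions per motif (scan units halved for palindromes)
    insertions: dict[str, int] = {}
    for name, total in config.motif_totals.items():
        palindromic = by_name[name].consensus == _revcomp_iupac(by_name[name].consensus)
        if palindromic:
            if total % 2:
                raise ValueError(
                    f"{name} is palindromic; its scan-unit total must be even"
                )
            insertions[name] = total // 2
        else:
            insertions[name] = total

    per_gene: dict[str, dict[str, int]] = {g: {} for g in gene_ids}
    for name, n_inst in sorted(insertions.items()):
        counts = rng.multinomial(n_inst, np.full(len(gene_ids), 1.0 / len(gene_ids)))
        for gene, k in zip(gene_ids, counts):
            if k:
                per_gene[gene][name] = int(k)

    promoters: dict[str, Promoter] = {}
    truth_counts: dict[str, dict[str, int]] = {}
    for gene in gene_ids:
        plan = per_gene[gene]
        expected = {m.name: 0 for m in library}
        for name, k in plan.items():
            palindromic = by_name[name].consensus == _revcomp_iupac(by_name[name].consensus)
            expected[name] = 2 * k if palindromic else k
        for attempt in range(20):
            background = _scrub_background(rng, config.promoter_length, library)
            seq = list(background)
            slots: list[tuple[int, int]] = []
            ok = True
            for name, k in sorted(plan.items()):
                width = len(by_name[name].consensus)
                for _ in range(k):
                    placed = False
                    for _try in range(200):
                        start = int(rng.integers(0, config.promoter_length - width + 1))
                        # keep >= 3 bp of background between instances so any
                        # spurious match must include a repairable background base
                        if all(start + width + 3 <= s or start >= e + 3 for s, e in slots):
                            inst = _instantiate_motif(rng, by_name[name], library)
                            if rng.random() < 0.5:
                                inst = _revcomp(inst)
                            seq[start : start + width] = inst
                            slots.append((start, start + width))
                            placed = True
                            break
                    if not placed:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            seq = _repair_junctions(rng, seq, slots, library, expected)
            if seq is None:
                continue
            promoter = Promoter(id=gene, seq="".join(seq), alphabet="dna")
            profile = scan_promoter(promoter, library)
            if profile.counts == expected:
                promoters[gene] = promoter
                truth_counts[gene] = dict(expected)
                break
        else:
            raise RuntimeError(f"could not assemble a clean promoter for {gene}")

    truth = {
        "per_gene_counts": truth_counts,
        "motif_totals": {
            name: sum(c.get(name, 0) for c in truth_counts.values())
            for name in by_name
        },
    }
    return promoters, truth


# --- genomes and annotation -------------------------------------------------


def _split_exons(
    rng: np.random.Generator, cds_len: int, n_exons: int
) -> list[int]:
    """Exon lengths (bp, summing to cds_len); each exon at least 9 bp."""
    if n_exons == 1:
        return [cds_len]
    while True:
        cuts = sorted(rng.choice(np.arange(1, cds_len), size=n_exons - 1, replace=False))
        lengths = np.diff([0, *cuts, cds_len])
        if (lengths >= 9).all():
            return [int(x) for x in lengths]


def _gff3_attrs(**kv: str) -> str:
    return ";".join(f"{k}={v}" for k, v in kv.items())


def make_family(
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FamilyData:
    """Two toy genomes realizing the configured family structure.

    Each gene sits on its own scaffold with its promoter embedded in the
    1500 bp upstream of the ATG (reverse-complemented for minus-strand
    genes), the CDS split into the planted number of exons, and a trailing
    stop codon.  Ground truth records every planted domain, pair, exon
    count and motif count.
    """
    if config is None:
        config = SimulationConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    gene_clade: dict[str, str] = {}
    gene_genome: dict[str, str] = {}
    gene_cds: dict[str, str] = {}
    gene_domains: dict[str, list[tuple[str, int, int]]] = {}
    pair_truth: list[dict] = []

    label = {"BBOX1": "B1", "BBOX2": "B2", "CCT": "CCT"}
    for spec in config.pair_plan:
        # evolution over long linkers can occasionally give birth to an
        # accidental domain; validate every member's scanned architecture
        # against the plant and re-evolve the lineage if it drifted
        for attempt in range(30):
            if spec.derive_b_from:
                # one-sided divergence from an existing gene; protect its
                # whole detected domain spans
                base = gene_cds[spec.derive_b_from]
                domains = gene_domains[spec.derive_b_from]
                protected = frozenset(
                    i for _, s, e in domains for i in range(s, e)
                )
                _, cds_b, ev_truth = evolve_pair(
                    base, spec.ks, spec.ka, rng,
                    protected_codons=protected, split=(0.0, 1.0),
                )
                members = {spec.gene_b: cds_b}
            else:
                protein, domains, anchors = build_clade_protein(
                    rng, spec.clade, spec.long_gene, spec.linker
                )
                anc_cds = reverse_translate(rng, protein)
                if spec.gene_b is None:
                    members, ev_truth = {spec.gene_a: anc_cds}, None
                else:
                    cds_a, cds_b, ev_truth = evolve_pair(
                        anc_cds, spec.ks, spec.ka, rng,
                        protected_codons=frozenset(anchors),
                    )
                    members = {spec.gene_a: cds_a, spec.gene_b: cds_b}
            expected_code = tuple(label[d] for d, _, _ in domains)
            scans = {
                gene: scan_all(SeqRecord(gene, translate_cds(cds), "protein"))
                for gene, cds in members.items()
            }
            if all(
                tuple(label[h.domain] for h in sorted(hits, key=lambda h: h.start))
                == expected_code
                for hits in scans.values()
            ):
                break
        else:
            raise RuntimeError(
                f"could not realize architecture {spec.clade} for {spec.gene_a}"
            )
        if spec.gene_b is not None:
            pair_truth.append(
                {
                    "id_a": min(spec.gene_a, spec.gene_b),
                    "id_b": max(spec.gene_a, spec.gene_b),
                    "relation": spec.relation,
                    "target_ks": spec.ks,
                    "target_ka": spec.ka,
                    "target_ratio": spec.ka / spec.ks if spec.ks else None,
                    **ev_truth,
                }
            )
        for gene, cds in members.items():
            gene_cds[gene] = cds
            gene_clade[gene] = spec.clade
            gene_genome[gene] = spec.genome_b if gene == spec.gene_b else spec.genome_a
            gene_domains[gene] = [
                (h.domain, h.start, h.end) for h in scans[gene]
            ]

    gene_ids = sorted(gene_cds)
    promoters, promoter_truth = make_promoters(config, gene_ids, rng)

    exon_counts: list[int] = []
    for k, n in sorted(config.exon_histogram.items()):
        exon_counts.extend([k] * n)
    rng.shuffle(exon_counts)
    exon_plan = dict(zip(gene_ids, exon_counts))

    genomes: dict[str, list[SeqRecord]] = {}
    gff3: dict[str, list[str]] = {}
    models: dict[str, list[GeneModel]] = {}
    proteins: dict[str, list[SeqRecord]] = {}
    cds_records: dict[str, list[SeqRecord]] = {}
    truth_genes: dict[str, dict] = {}

    scaffold_index: dict[str, int] = {}
    for gene in gene_ids:
        genome = gene_genome[gene]
        genomes.setdefault(genome, [])
        gff3.setdefault(genome, ["##gff-version 3"])
        models.setdefault(genome, [])
        proteins.setdefault(genome, [])
        cds_records.setdefault(genome, [])
        scaffold_index[genome] = scaffold_index.get(genome, 0) + 1
        scaffold_id = f"{genome}_scaffold{scaffold_index[genome]:03d}"

        cds = gene_cds[gene] + "TAA"
        n_exons = exon_plan[gene]
        exon_lengths = _split_exons(rng, len(cds), n_exons)
        intron_lengths = [int(rng.integers(80, 301)) for _ in range(n_exons - 1)]
        upstream_pad = int(rng.integers(100, 401))
        downstream_pad = int(rng.integers(100, 301))
        strand = "-" if rng.random() < 0.35 else "+"

        # assemble on the coding (plus) orientation first
        parts = ["".join(rng.choice(list("ACGT"), size=upstream_pad)),
                 promoters[gene].seq]
        exon_coords: list[tuple[int, int]] = []
        offset = upstream_pad + len(promoters[gene].seq)
        pos = 0
        for i, ex_len in enumerate(exon_lengths):
            exon_coords.append((offset, offset + ex_len))
            parts.append(cds[pos : pos + ex_len])
            pos += ex_len
            offset += ex_len
            if i < len(intron_lengths):
                parts.append("".join(rng.choice(list("ACGT"), size=intron_lengths[i])))
                offset += intron_lengths[i]
        parts.append("".join(rng.choice(list("ACGT"), size=downstream_pad)))
        scaffold_seq = "".join(parts)

        if strand == "-":
            L = len(scaffold_seq)
            scaffold_seq = _revcomp(scaffold_seq)
            exon_coords = [(L - e, L - s) for s, e in reversed(exon_coords)]

        genomes[genome].append(SeqRecord(scaffold_id, scaffold_seq, "dna"))
        gene_start = min(s for s, _ in exon_coords)
        gene_end = max(e for _, e in exon_coords)

        lines = gff3[genome]
        lines.append(
            "\t".join([scaffold_id, "bbxkit_sim", "gene", str(gene_start + 1),
                       str(gene_end), ".", strand, ".", _gff3_attrs(ID=gene)])
        )
        mrna_id = f"{gene}.t1"
        lines.append(
            "\t".join([scaffold_id, "bbxkit_sim", "mRNA", str(gene_start + 1),
                       str(gene_end), ".", strand, ".",
                       _gff3_attrs(ID=mrna_id, Parent=gene)])
        )
        phase = 0
        ordered = exon_coords if strand == "+" else list(reversed(exon_coords))
        for i, (s, e) in enumerate(sorted(exon_coords)):
            lines.append(
                "\t".join([scaffold_id, "bbxkit_sim", "exon", str(s + 1), str(e),
                           ".", strand, ".",
                           _gff3_attrs(ID=f"{mrna_id}.exon{i+1}", Parent=mrna_id)])
            )
        for i, (s, e) in enumerate(ordered):  # transcription order for phase
            lines.append(
                "\t".join([scaffold_id, "bbxkit_sim", "CDS", str(s + 1), str(e),
                           ".", strand, str(phase),
                           _gff3_attrs(ID=f"{mrna_id}.cds{i+1}", Parent=mrna_id)])
            )
            phase = (3 - ((e - s) - phase) % 3) % 3

        prot = translate_cds(cds)
        models[genome].append(
            GeneModel(
                gene_id=gene, seq_id=scaffold_id, start=gene_start, end=gene_end,
                strand=strand, exons=sorted(exon_coords),
                cds_regions=sorted(exon_coords), cds=cds, protein=prot,
                complete=True,
            )
        )
        proteins[genome].append(SeqRecord(gene, prot, "protein"))
        cds_records[genome].append(SeqRecord(gene, cds, "dna"))
        truth_genes[gene] = {
            "genome": genome,
            "clade": gene_clade[gene],
            "architecture": tuple(
                {"BBOX1": "B1", "BBOX2": "B2", "CCT": "CCT"}[d]
                for d, _, _ in gene_domains[gene]
            ),
            "domains": gene_domains[gene],
            "exon_count": n_exons,
            "strand": strand,
            "scaffold": scaffold_id,
        }

    truth = {
        "genes": truth_genes,
        "pairs": pair_truth,
        "promoters": promoter_truth,
        "n_genes": {g: len(models[g]) for g in models},
    }
    return FamilyData(
        genomes=genomes,
        gff3={g: "\n".join(lines) + "\n" for g, lines in gff3.items()},
        proteins=proteins,
        cds=cds_records,
        models=models,
        promoters=promoters,
        truth=truth,
    )


# --- expression -------------------------------------------------------------


def make_fpkm(
    config: SimulationConfig,
    gene_ids: list[str] | None = None,
    rng: np.random.Generator | None = None,
):
    """A genes x 8-tissue FPKM matrix with a planted A/B/C group structure.

    Group A genes are broadly expressed (all tissues well above the mid-low
    cutoff), group B basically silent (FPKM < 1 in at least 7 tissues) and
    group C similarly low-expressed.  Returns (DataFrame, truth).
    """
    import pandas as pd

    from .expression import TISSUES

    if rng is None:
        rng = np.random.default_rng(config.seed)
    if gene_ids is None:
        gene_ids = [f"DoBBX{i:02d}" for i in range(1, 20)]
    n_a, n_b, n_c = config.fpkm_group_sizes
    if n_a + n_b + n_c != len(gene_ids):
        raise ValueError("group sizes must sum to the gene count")
    order = list(gene_ids)
    rng.shuffle(order)
    groups = {}
    rows = {}
    for i, gene in enumerate(order):
        if i < n_a:
            groups[gene] = "A"
            values = 10.0 ** rng.uniform(1.0, 1.8, size=len(TISSUES))
        elif i < n_a + n_b:
            groups[gene] = "B"
            values = rng.uniform(0.0, 0.8, size=len(TISSUES))
            if rng.random() < 0.4:  # one leaky tissue still leaves >= 7 silent
                values[rng.integers(len(TISSUES))] = rng.uniform(1.0, 2.0)
        else:
            groups[gene] = "C"
            values = rng.uniform(1.2, 6.0, size=len(TISSUES))
        rows[gene] = np.round(values, 4)
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(TISSUES))
    matrix = matrix.loc[gene_ids]
    truth = {"groups": groups, "group_sizes": dict(zip("ABC", (n_a, n_b, n_c)))}
    return matrix, truth


def make_qpcr(
    config: SimulationConfig,
    gene_ids: list[str] | None = None,
    rng: np.random.Generator | None = None,
):
    """A replicated Ct table with planted fold changes.

    Ct model: the reference gene is flat (Ct ~= 18); the target's
    control dCt is a per-gene baseline, and treatment shifts it by
    -log2(true fold) plus Normal(0, sd) replicate noise.  Returns
    (records, truth) where records are :class:`~bbxkit.expression.QpcrRecord`
    objects and truth maps (gene, treatment, timepoint) to the true fold.
    """
    from .expression import QpcrRecord

    if rng is None:
        rng = np.random.default_rng(config.seed)
    if gene_ids is None:
        gene_ids = [f"DoBBX{i:02d}" for i in range(1, 20)]
    sd = config.ct_noise_sd
    n_rep = config.n_replicates
    records = []
    truth: dict[tuple[str, str, int], float] = {}
    for gene in gene_ids:
        base_dct = float(rng.uniform(4.0, 10.0))
        for treatment in TREATMENTS:
            control_ref = 18.0 + rng.normal(0.0, 0.1, size=n_rep)
            control_target = control_ref + base_dct + rng.normal(0.0, sd, size=n_rep)
            for timepoint in TIMEPOINTS:
                key = (gene, treatment, timepoint)
                fold = config.qpcr_folds.get(key)
                if fold is None:
                    fold = float(2.0 ** rng.normal(0.0, 1.2))
                truth[key] = fold
                ref = 18.0 + rng.normal(0.0, 0.1, size=n_rep)
                target = ref + base_dct - math.log2(fold) + rng.normal(0.0, sd, size=n_rep)
                records.append(
                    QpcrRecord(
                        gene_id=gene,
                        treatment=treatment,
                        timepoint=timepoint,
                        ct_target=[round(x, 4) for x in target],
                        ct_reference=[round(x, 4) for x in ref],
                        control_ct_target=[round(x, 4) for x in control_target],
                        control_ct_reference=[round(x, 4) for x in control_ref],
                    )
                )
    return records, truth
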