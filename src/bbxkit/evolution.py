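"""Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction and window scans.

The NG86 method counts, for every codon, the expected fraction of the three
possible mutations at each position that are synonymous ("sites"), and for
every codon pair the average synonymous/nonsynonymous difference counts over
all minimal mutational pathways.  Pathways passing through stop codons are
excluded; mutations to stop codons are excluded from the site denominators,
so synonymous + nonsynonymous sites always sum to exactly 3 per codon.
Proportions are corrected for multiple hits with the one-parameter
Jukes–Cantor formula d = -(3/4) ln(1 - (4/3) p).

Selection classes follow the conventional Ka/Ks bins (< 0.3 strong
purifying, 0.3–1 inclusive relaxed purifying, > 1 positive), and duplication
ages follow the synonymous-clock convention that homolog pairs with Ks near
1 trace to the shared orchid whole-genome duplication while Ks < 0.2 marks
recent duplicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

from .homology import AlignmentResult, HomologPair

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "WindowProfile",
    "codon_align",
    "ng86_sites",
    "ng86_differences",
    "kaks",
    "sliding_window",
    "classify_selection",
    "classify_duplication",
    "SENSE_CODONS",
    "GENETIC_CODE",
    "STOP_CODONS",
]

log = logging.getLogger(__name__)

GAP_CODON = "---"
NUCLEOTIDES = "ACGT"
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))

MIN_CODONS_DEFAULT = 10  # minimum ungapped codon columns for a Ka/Ks estimate
SATURATION_P = 0.75  # Jukes-Cantor correction diverges at p = 3/4

SELECTION_BINS = ((0.3, "strong_purifying", "<0.3"), (1.0, "relaxed_purifying", "0.3-1"))
WGD_KS_BOUNDS = (0.8, 1.6)
RECENT_KS_MAX = 0.2


@dataclass
class CodonAlignment:
    pair: HomologPair | None
    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon sequences must have equal aligned length")

    def __len__(self) -> int:
        return len(self.codons_a)

    def ungapped_columns(self) -> list[tuple[str, str]]:
        return [
            (ca, cb)
            for ca, cb in zip(self.codons_a, self.codons_b)
            if ca != GAP_CODON and cb != GAP_CODON
        ]


@dataclass
class KaKsResult:
    pair: HomologPair | None
    ka: float | None
    ks: float | None
    ratio: float | None
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    n_codons: int
    saturated: bool = False
    selection_class: str = "undetermined"
    duplication_class: str | None = None


@dataclass
class WindowProfile:
    pair: HomologPair | None
    window_bp: int
    step_bp: int
    windows: list[tuple[int, int, float | None, float | None, float | None]]
    whole_length_fallback: bool = False


def codon_align(cds_a: str, cds_b: str, protein_alignment: AlignmentResult) -> CodonAlignment:
    """Back-translate a protein alignment onto the two coding sequences.

    The trailing stop codon, if present, is stripped; every protein gap
    becomes one gap codon.  A CDS that does not encode its aligned protein
    raises, naming the first discordant codon.
    """
    from .core_io import translate_cds

    def strip_stop(cds: str) -> str:
        if len(cds) % 3:
            raise ValueError("CDS length is not a multiple of 3")
        return cds[:-3] if cds[-3:].upper() in STOP_CODONS else cds

    def back_translate(cds: str, gapped: str, label: str) -> list[str]:
        cds = strip_stop(cds.upper())
        protein = translate_cds(cds)
        degapped = gapped.replace("-", "")
        if protein != degapped:
            for i, (x, y) in enumerate(zip(protein, degapped)):
                if x != y:
                    raise ValueError(
                        f"{label}: codon {i} ({cds[3*i:3*i+3]}) translates to {x}, "
                        f"aligned protein has {y}"
                    )
            raise ValueError(f"{label}: CDS/protein length mismatch")
        out, idx = [], 0
        for aa in gapped:
            if aa == "-":
                out.append(GAP_CODON)
            else:
                out.append(cds[3 * idx : 3 * idx + 3])
                idx += 1
        return out

    pair = None
    codons_a = back_translate(cds_a, protein_alignment.aligned_a, protein_alignment.id_a)
    codons_b = back_translate(cds_b, protein_alignment.aligned_b, protein_alignment.id_b)
    return CodonAlignment(pair, codons_a, codons_b)


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes one site, split by the synonymous fraction of
    its legal (non-stop) single-nucleotide mutations; the two counts
    therefore sum to exactly 3.
    """
    codon = codon.upper()
    if codon not in GENETIC_CODE:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = n_legal = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            n_legal += 1
            if GENETIC_CODE[mutant] == aa:
                n_syn += 1
        syn += n_syn / n_legal if n_legal else 0.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd): pathway-averaged synonymous/nonsynonymous differences.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are dropped and the average is renormalized
    over the legal ones.  If no legal pathway exists the column is
    uncountable and (nan, nan) is returned so callers can skip it.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c not in GENETIC_CODE:
            raise ValueError(f"not a sense codon: {c!r}")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    total_syn = total_nonsyn = 0.0
    n_legal_paths = 0
    for order in permutations(diff_positions):
        current = codon_a
        path_syn = path_nonsyn = 0.0
        legal = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                legal = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                path_syn += 1
            else:
                path_nonsyn += 1
            current = nxt
        if legal:
            n_legal_paths += 1
            total_syn += path_syn
            total_nonsyn += path_nonsyn
    if n_legal_paths == 0:
        return math.nan, math.nan
    return total_syn / n_legal_paths, total_nonsyn / n_legal_paths


def _jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when the proportion is at/beyond saturation."""
    if p >= SATURATION_P:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _kaks_from_columns(columns: list[tuple[str, str]], pair: HomologPair | None) -> KaKsResult:
    s_a = n_a = s_b = n_b = sd = nd = 0.0
    n_codons = 0
    for ca, cb in columns:
        if ca in STOP_CODONS or cb in STOP_CODONS:
            log.warning("stop codon in alignment column (%s/%s); skipped", ca, cb)
            continue
        d_s, d_n = ng86_differences(ca, cb)
        if math.isnan(d_s):
            log.info("column %s/%s has no stop-free pathway; skipped", ca, cb)
            continue
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        sd += d_s
        nd += d_n
        n_codons += 1
    s_sites = 0.5 * (s_a + s_b)
    n_sites = 0.5 * (n_a + n_b)
    result = KaKsResult(
        pair=pair, ka=None, ks=None, ratio=None,
        s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd, n_codons=n_codons,
    )
    if n_codons == 0:
        return result
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    result.ks, result.ka = ks, ka
    if ks is None or ka is None:
        result.saturated = True
        return result
    if ks > 0:
        result.ratio = ka / ks
        result.selection_class = classify_selection(result.ratio)[0]
        result.duplication_class = classify_duplication(ks)
    return result


def kaks(
    aln: CodonAlignment, min_codons: int = MIN_CODONS_DEFAULT
) -> KaKsResult:
    """Whole-alignment NG86 Ka/Ks with JC correction.

    Gapped codon columns are skipped.  Identical sequences yield
    Ka = Ks = 0 with an undefined (0/0) ratio; a synonymous proportion at or
    beyond 3/4 flags the estimate as saturated and leaves the ratio
    undefined.
    """
    columns = aln.ungapped_columns()
    if len(columns) < min_codons:
        raise ValueError(
            f"only {len(columns)} ungapped codon columns; need >= {min_codons}"
        )
    return _kaks_from_columns(columns, aln.pair)


def sliding_window(
    aln: CodonAlignment, window_bp: int = 150, step_bp: int = 9
) -> WindowProfile:
    """Ka/Ks profile in windows advancing over the aligned coordinate system.

    The window (150 bp = 50 codons by default) and step (9 bp = 3 codons)
    are interpreted in alignment space; windows span whole codons, and
    window count = floor((L - window) / step) + 1.  An alignment shorter
    than one window yields a single whole-length, flagged window.
    """
    if window_bp % 3 or step_bp % 3:
        raise ValueError("window and step must span whole codons (multiples of 3)")
    length_bp = 3 * len(aln)
    win_c, step_c = window_bp // 3, step_bp // 3
    fallback = length_bp < window_bp
    if fallback:
        starts = [0]
        win_c = len(aln)
    else:
        n_windows = (length_bp - window_bp) // step_bp + 1
        starts = [i * step_c for i in range(n_windows)]
    windows = []
    for start_c in starts:
        cols = [
            (ca, cb)
            for ca, cb in zip(
                aln.codons_a[start_c : start_c + win_c],
                aln.codons_b[start_c : start_c + win_c],
            )
            if ca != GAP_CODON and cb != GAP_CODON
        ]
        res = _kaks_from_columns(cols, aln.pair)
        windows.append((3 * start_c, 3 * (start_c + win_c), res.ka, res.ks, res.ratio))
    return WindowProfile(aln.pair, window_bp, step_bp, windows, fallback)


def classify_selection(ratio: float | None) -> tuple[str, str]:
    """(selection class, bin label) for a Ka/Ks ratio.

    Bins are left-closed: 0.3 falls in "0.3-1", 1.0 is still relaxed
    purifying, and only ratios strictly above 1 count as positive selection.
    """
    if ratio is None or math.isnan(ratio):
        return "undetermined", "undefined"
    if ratio < 0:
        raise ValueError("Ka/Ks ratio cannot be negative")
    for bound, label, bin_label in SELECTION_BINS:
        if ratio < bound or (bound == 1.0 and ratio == 1.0):
            return label, bin_label
    return "positive", ">1"


def classify_duplication(
    ks: float | None,
    wgd_bounds: tuple[float, float] = WGD_KS_BOUNDS,
    recent_max: float = RECENT_KS_MAX,
) -> str:
    """Age class of a duplication from its synonymous divergence."""
    if ks is None or math.isnan(ks):
        return "other"
    if wgd_bounds[0] <= ks <= wgd_bounds[1]:
        return "shared_WGD"
    if ks < recent_max:
        return "recent"
    return "other"
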