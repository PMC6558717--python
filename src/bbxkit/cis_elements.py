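"""Promoter scanning against a library of named plant cis-acting elements.

The library (shipped as ``data/motifs.tsv``) holds literal/IUPAC consensus
strings for the classic plant promoter elements in three categories —
development, hormone and stress response.  Scanning is exact IUPAC matching
on one or both strands; all (possibly overlapping) occurrences count.  In
strict mode (default) an N in the promoter never matches anything, so
low-quality sequence cannot inflate counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from Bio.Seq import Seq

from .core_io import SeqRecord

__all__ = [
    "MotifDefinition",
    "PromoterProfile",
    "load_motif_library",
    "scan_promoter",
    "aggregate_profiles",
    "CATEGORIES",
]

CATEGORIES = ("development", "hormone", "stress")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    consensus: str
    category: str
    function_note: str = ""

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"{self.name}: empty consensus")
        bad = set(self.consensus.upper()) - set(_IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC symbols {sorted(bad)}")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")


@dataclass
class PromoterProfile:
    gene_id: str
    counts: dict[str, int] = field(default_factory=dict)
    category_sums: dict[str, int] = field(default_factory=dict)
    category_ratios: dict[str, dict[str, float]] = field(default_factory=dict)


def load_motif_library(path: str | None = None) -> list[MotifDefinition]:
    """Load the built-in motif table, or a user TSV with the same columns."""
    if path is None:
        source = resources.files("bbxkit").joinpath("data/motifs.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"name", "consensus", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"motif table missing columns: {sorted(missing)}")
    return [
        MotifDefinition(
            row["name"],
            str(row["consensus"]).upper(),
            row["category"],
            str(row.get("function_note", "")),
        )
        for _, row in df.iterrows()
    ]


def _motif_regex(consensus: str, strict_n: bool = True) -> re.Pattern:
    # lookahead so overlapping occurrences all count
    parts = []
    for sym in consensus.upper():
        allowed = _IUPAC[sym]
        if not strict_n:  # permissive: promoter Ns may stand for any base
            allowed += "N"
        parts.append(f"[{allowed}]" if len(allowed) > 1 else allowed)
    return re.compile("(?=" + "".join(parts) + ")")


def count_matches(sequence: str, consensus: str, strands: str = "both", strict_n: bool = True) -> int:
    """Number of (overlapping) IUPAC matches on the requested strand(s)."""
    seq = sequence.upper()
    pattern = _motif_regex(consensus, strict_n)
    total = len(pattern.findall(seq))
    if strands == "both":
        total += len(pattern.findall(str(Seq(seq).reverse_complement())))
    elif strands != "plus":
        raise ValueError("strands must be 'plus' or 'both'")
    return total


def _finalize_profile(profile: PromoterProfile, library: list[MotifDefinition]) -> None:
    for cat in CATEGORIES:
        members = [m for m in library if m.category == cat]
        total = sum(profile.counts.get(m.name, 0) for m in members)
        profile.category_sums[cat] = total
        profile.category_ratios[cat] = {
            m.name: (profile.counts.get(m.name, 0) / total if total else 0.0)
            for m in members
        }


def scan_promoter(
    promoter: SeqRecord,
    library: list[MotifDefinition] | None = None,
    strands: str = "both",
    strict_n: bool = True,
) -> PromoterProfile:
    """Count all library motifs in one promoter (case-insensitive).

    An empty promoter (a gene flush against its scaffold edge) yields an
    all-zero profile rather than an error.
    """
    if library is None:
        library = load_motif_library()
    profile = PromoterProfile(gene_id=promoter.id)
    for motif in library:
        profile.counts[motif.name] = (
            count_matches(promoter.seq, motif.consensus, strands, strict_n)
            if promoter.seq
            else 0
        )
    _finalize_profile(profile, library)
    return profile


def aggregate_profiles(
    profiles: list[PromoterProfile],
    library: list[MotifDefinition] | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Cohort summaries: the gene x motif count grid, per-category totals,
    and the within-category share of each motif (shares in a category sum
    to 1 whenever the category total is positive)."""
    if not profiles:
        raise ValueError("need at least one promoter profile")
    if library is None:
        library = load_motif_library()
    motif_names = [m.name for m in library]
    grid = pd.DataFrame(
        [[p.counts.get(name, 0) for name in motif_names] for p in profiles],
        index=[p.gene_id for p in profiles],
        columns=motif_names,
    )
    by_cat = {m.name: m.category for m in library}
    motif_totals = grid.sum(axis=0)
    category_sums = pd.Series(
        {cat: int(motif_totals[[n for n in motif_names if by_cat[n] == cat]].sum())
         for cat in CATEGORIES},
        name="total",
    )
    rows = []
    for name in motif_names:
        cat = by_cat[name]
        total = category_sums[cat]
        rows.append(
            {
                "motif": name,
                "category": cat,
                "count": int(motif_totals[name]),
                "ratio": float(motif_totals[name] / total) if total else 0.0,
            }
        )
    ratios = pd.DataFrame(rows).set_index("motif")
    return grid, category_sums, ratios
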