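"""Tissue expression (FPKM) summaries and qRT-PCR relative expression.

FPKM values are binned with the fixed cutpoints used for the tissue heatmap
(left-closed): [0,1) not expressed, [1,6.8) low, [6.8,17.5) mid-low,
[17.5,44.7) mid-high, [44.7,inf) high.  Genes are grouped by overall tissue
pattern: group A = modest-to-high expression everywhere (median FPKM >= 6.8
across tissues), group B = essentially silent (FPKM < 1 in at least 7 of 8
tissues), group C = the rest (similar low expression).  Those thresholds
formalize qualitative group descriptions and are exposed as parameters.

qRT-PCR fold changes use the 2^-ddCt estimator: per-replicate
dCt = Ct_target - Ct_reference, ddCt = mean dCt(treated) - mean dCt(control),
fold = 2^-ddCt, with a two-sided Welch t-test on the replicate dCt values
for the significance stars (** p < 0.01, * p < 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TISSUES",
    "FPKM_BINS",
    "QpcrRecord",
    "FoldChangeResult",
    "bin_fpkm",
    "bin_matrix",
    "group_genes",
    "tissue_venn",
    "relative_expression",
]

TISSUES = (
    "root", "root_tips", "stem", "leaf", "speal", "column", "lip", "flower_buds",
)

# (upper bound, label); bins are left-closed, the last is unbounded
FPKM_BINS = (
    (1.0, "not_expressed"),
    (6.8, "low"),
    (17.5, "mid_low"),
    (44.7, "mid_high"),
    (math.inf, "high"),
)

MAX_VENN_SETS = 6  # beyond this a Venn is unreadable and almost surely a bug


def bin_fpkm(value: float) -> str:
    """Expression bin label for one FPKM value (left-closed boundaries)."""
    if value < 0 or math.isnan(value):
        raise ValueError(f"FPKM must be non-negative, got {value}")
    for bound, label in FPKM_BINS:
        if value < bound:
            return label
    raise AssertionError("unreachable: bins partition [0, inf)")


def bin_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Element-wise bin labels for a genes x tissues FPKM matrix."""
    return matrix.map(bin_fpkm)


def group_genes(
    matrix: pd.DataFrame,
    a_median_fpkm: float = 6.8,
    b_max_fpkm: float = 1.0,
    b_min_tissues: int = 7,
) -> dict[str, str]:
    """Assign each gene a tissue-pattern group: A (broadly expressed),
    B (basically not expressed) or C (the remainder)."""
    groups: dict[str, str] = {}
    for gene, row in matrix.iterrows():
        values = row.to_numpy(dtype=float)
        if np.median(values) >= a_median_fpkm:
            groups[gene] = "A"
        elif (values < b_max_fpkm).sum() >= b_min_tissues:
            groups[gene] = "B"
        else:
            groups[gene] = "C"
    return groups


def tissue_venn(
    matrix: pd.DataFrame,
    tissues: list[str] | None = None,
    expressed_threshold: float = 1.0,
) -> dict[frozenset, int]:
    """Exclusive Venn-region counts of expressed genes over tissue sets.

    A gene is expressed in a tissue iff FPKM >= threshold.  The returned
    mapping keys each non-empty tissue combination to the number of genes
    expressed in exactly those tissues; region counts sum to the union size.
    """
    if tissues is None:
        tissues = list(matrix.columns)
    if len(tissues) > MAX_VENN_SETS:
        raise ValueError(f"at most {MAX_VENN_SETS} tissue sets supported")
    expressed = {
        t: set(matrix.index[matrix[t] >= expressed_threshold]) for t in tissues
    }
    regions: dict[frozenset, int] = {}
    union = set().union(*expressed.values()) if expressed else set()
    for gene in union:
        membership = frozenset(t for t in tissues if gene in expressed[t])
        regions[membership] = regions.get(membership, 0) + 1
    return regions


def venn_intersections(
    matrix: pd.DataFrame,
    tissues: list[str] | None = None,
    expressed_threshold: float = 1.0,
) -> dict[frozenset, int]:
    """Plain intersection sizes for every tissue combination (not exclusive)."""
    if tissues is None:
        tissues = list(matrix.columns)
    if len(tissues) > MAX_VENN_SETS:
        raise ValueError(f"at most {MAX_VENN_SETS} tissue sets supported")
    expressed = {
        t: set(matrix.index[matrix[t] >= expressed_threshold]) for t in tissues
    }
    out: dict[frozenset, int] = {}
    for k in range(1, len(tissues) + 1):
        for combo in combinations(tissues, k):
            out[frozenset(combo)] = len(set.intersection(*(expressed[t] for t in combo)))
    return out


@dataclass
class QpcrRecord:
    """Ct replicates for one gene/treatment/timepoint plus its control."""

    gene_id: str
    treatment: str
    timepoint: int  # hours
    ct_target: list[float]
    ct_reference: list[float]
    control_ct_target: list[float]
    control_ct_reference: list[float]

    def __post_init__(self) -> None:
        for values in (self.ct_target, self.ct_reference,
                       self.control_ct_target, self.control_ct_reference):
            for ct in values:
                if not 0 < ct < 45:
                    raise ValueError(f"Ct value {ct} outside the plausible (0, 45) range")
        if len(self.ct_target) != len(self.ct_reference):
            raise ValueError("target and reference replicate counts differ")
        if len(self.control_ct_target) != len(self.control_ct_reference):
            raise ValueError("control target/reference replicate counts differ")


@dataclass
class FoldChangeResult:
    gene_id: str
    treatment: str
    timepoint: int
    fold_change: float
    direction: str  # {"up", "down", "unchanged"}
    p_value: float
    significance: str  # {"ns", "*", "**"}


def relative_expression(record: QpcrRecord) -> FoldChangeResult:
    """2^-ddCt fold change with a Welch t-test on replicate dCt values.

    Fewer than 2 replicates on either side is an error; exactly 2 computes
    with a warning (the design calls for 3 biological replicates).
    """
    d_treated = np.asarray(record.ct_target) - np.asarray(record.ct_reference)
    d_control = np.asarray(record.control_ct_target) - np.asarray(record.control_ct_reference)
    for name, d in (("treated", d_treated), ("control", d_control)):
        if len(d) < 2:
            raise ValueError(f"{record.gene_id}: fewer than 2 {name} replicates")
        if len(d) < 3:
            warnings.warn(
                f"{record.gene_id}: only {len(d)} {name} replicates", stacklevel=2
            )
    ddct = float(d_treated.mean() - d_control.mean())
    fold = 2.0 ** (-ddct)
    if np.allclose(d_treated.var(ddof=1) + d_control.var(ddof=1), 0.0):
        p = 1.0 if math.isclose(ddct, 0.0, abs_tol=1e-12) else 0.0
    else:
        p = float(stats.ttest_ind(d_treated, d_control, equal_var=False).pvalue)
    if p < 0.01:
        significance = "**"
    elif p < 0.05:
        significance = "*"
    else:
        significance = "ns"
    if math.isclose(fold, 1.0, rel_tol=1e-9):
        direction = "unchanged"
    else:
        direction = "up" if fold > 1.0 else "down"
    return FoldChangeResult(
        record.gene_id, record.treatment, record.timepoint,
        fold, direction, p, significance,
    )
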