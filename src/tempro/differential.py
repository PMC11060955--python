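"""Differential expression with pseudo-count fold changes.

Fold changes are ratios of group means after adding a pseudo value of 0.1,
which buffers low-abundance proteins and avoids division by zero.
Significance comes from a two-sided equal-variance Student's t test (per-gene)
with Benjamini–Hochberg correction within each contrast; a Kruskal–Wallis H
test handles comparisons across more than two groups (phases or tissues).
A gene is called up if FC ≥ threshold (default 2) with adjusted p < 0.05,
down if FC ≤ 1/threshold; a 10-fold variant is obtained by raising the
threshold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_PSEUDO = 0.1


def fold_change(group_a, group_b, pseudo: float = DEFAULT_PSEUDO) -> float:
    """(mean_a + pseudo) / (mean_b + pseudo); strictly positive."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative expression values")
    return float((a.mean() + pseudo) / (b.mean() + pseudo))


def student_t(group_a, group_b, equal_var: bool = True) -> float:
    """Two-sided two-sample t-test p-value.

    Identical zero-variance groups give p = 1 (no evidence of difference)
    instead of an undefined statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    return float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    All-identical observations give (0, 1): the rank test carries no
    information in that degenerate case.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


_CONTRAST_RE = re.compile(r"^\s*(\w+):D(\d+)\s+vs\s+(?:(\w+):)?D(\d+)\s*$")


def parse_contrast(label: str) -> tuple[tuple[str, int], tuple[str, int]]:
    """Parse labels like ``"tumor:D3 vs tumor:D0"`` or ``"LN:D7 vs D0"``."""
    m = _CONTRAST_RE.match(label)
    if not m:
        raise ValueError(f"cannot parse contrast {label!r}")
    tissue_a, day_a, tissue_b, day_b = m.groups()
    return (tissue_a, int(day_a)), (tissue_b or tissue_a, int(day_b))


@dataclass
class Contrast:
    label: str
    samples_a: list[str]
    samples_b: list[str]


def resolve_contrast(design: pd.DataFrame, label: str) -> Contrast:
    (ta, da), (tb, db) = parse_contrast(label)
    sa = design.loc[(design.tissue == ta) & (design.day == da), "sample_id"].tolist()
    sb = design.loc[(design.tissue == tb) & (design.day == db), "sample_id"].tolist()
    if not sa or not sb:
        raise ValueError(f"contrast {label!r}: no samples for one side")
    return Contrast(label, sa, sb)


def call_differential(
    values: pd.DataFrame,
    design: pd.DataFrame,
    contrast: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudo: float = DEFAULT_PSEUDO,
) -> pd.DataFrame:
    """Per-gene differential table for one contrast.

    Columns: mean_a, mean_b, fold_change, log2_fc, p_value, adj_p, call.
    BH correction is applied within this contrast.  ``fc_threshold=10``
    yields the 10-fold variant used for the sharpest early-implantation
    contrast.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    c = resolve_contrast(design, contrast)
    A = values[c.samples_a].to_numpy(dtype=float)
    B = values[c.samples_b].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    fc = (mean_a + pseudo) / (mean_b + pseudo)
    pvals = np.array([student_t(A[i], B[i]) for i in range(len(values))])
    adj = bh_adjust(pvals)
    call = np.where(
        (fc >= fc_threshold) & (adj < alpha), "up",
        np.where((fc <= 1.0 / fc_threshold) & (adj < alpha), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "contrast": c.label,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "log2_fc": np.log2(fc),
            "p_value": pvals,
            "adj_p": adj,
            "call": call,
        },
        index=values.index,
    )
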