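"""Expression-based drug-target prioritization.

A gene is a tumor-high candidate when (1) a Kruskal–Wallis test across the
four tissues' samples is significant after BH adjustment (adj p < 0.05) and
(2) its mean tumor abundance exceeds 1.2 times the mean of each of the three
immune organs individually.  Candidates are joined to a drug-annotation
table (clinical status, functional categories) and category percentages are
reported with one-decimal rounding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tempro.differential import bh_adjust, kruskal_wallis

DRUG_COLUMNS = ["gene", "druggable", "status", "categories"]
STATUS_LEVELS = ("approved", "phase3", "phase1_2")
CATEGORY_LEVELS = ("driver", "cell_cycle", "apoptosis", "metabolic")


def prioritize_targets(
    values: pd.DataFrame,
    design: pd.DataFrame,
    drug_table: pd.DataFrame,
    alpha: float = 0.05,
    ratio: float = 1.2,
    tumor: str = "tumor",
) -> pd.DataFrame:
    """Per-gene KW statistics, tumor/immune-organ ratios, and selection calls.

    Tissue means pool all days and replicates.  Returns one row per gene
    with columns kw_h, kw_p, kw_adj_p, mean_<tissue>..., min_ratio,
    tumor_high (KW + ratio rule), druggable, status, categories, and
    selected = tumor_high AND druggable.
    """
    tissues = sorted(design["tissue"].unique())
    if tumor not in tissues:
        raise ValueError(f"tissue {tumor!r} missing from design")
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues")
    cols = {t: design.loc[design["tissue"] == t, "sample_id"].tolist() for t in tissues}
    for t, ids in cols.items():
        if not ids:
            raise ValueError(f"tissue {t} has no samples")

    stats_rows = []
    for gene in values.index:
        groups = [values.loc[gene, ids].to_numpy(dtype=float) for ids in cols.values()]
        h, p = kruskal_wallis(*groups)
        row = {"gene": gene, "kw_h": h, "kw_p": p}
        for t, g in zip(cols, groups):
            row[f"mean_{t}"] = float(np.mean(g))
        stats_rows.append(row)
    out = pd.DataFrame(stats_rows).set_index("gene")
    out["kw_adj_p"] = bh_adjust(out["kw_p"])

    others = [t for t in tissues if t != tumor]
    other_means = out[[f"mean_{t}" for t in others]].to_numpy(dtype=float)
    tumor_mean = out[f"mean_{tumor}"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = tumor_mean[:, None] / other_means
    ratios = np.where(other_means == 0, np.inf, ratios)
    ratios = np.where((other_means == 0) & (tumor_mean[:, None] == 0), 0.0, ratios)
    out["min_ratio"] = ratios.min(axis=1)
    out["tumor_high"] = (out["kw_adj_p"] < alpha) & (out["min_ratio"] > ratio)

    annot = drug_table.set_index("gene").reindex(out.index)
    out["druggable"] = annot["druggable"].fillna(False).astype(bool)
    out["status"] = annot["status"].fillna("other")
    out["categories"] = annot["categories"].fillna("")
    out["selected"] = out["tumor_high"] & out["druggable"]
    return out


def summarize_categories(counts: dict[str, int], total: int) -> pd.DataFrame:
    """Count and one-decimal percentage per category.

    ``counts`` maps category name to member count within a selection of
    ``total`` candidates; percentages are round(100·count/total, 1).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    rows = [
        {"category": k, "count": int(v),
         "percent": float(np.round(100.0 * v / total, 1))}
        for k, v in counts.items()
    ]
    return pd.DataFrame(rows).set_index("category")


def summarize_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    """Category breakdown of the selected (tumor-high, druggable) candidates."""
    sel = candidates[candidates["selected"]]
    if sel.empty:
        raise ValueError("no selected candidates to summarize")
    counts: dict[str, int] = {}
    for s in STATUS_LEVELS:
        counts[s] = int((sel["status"] == s).sum())
    cat_lists = sel["categories"].fillna("").str.split(";")
    for c in CATEGORY_LEVELS:
        counts[c] = int(cat_lists.apply(lambda cats: c in cats).sum())
    return summarize_categories(counts, len(sel))
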