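"""Local gene-set over-representation and functional trajectory scores.

Over-representation uses the upper-tail hypergeometric test with the detected
proteome as background (gene sets are intersected with the background before
testing), BH-corrected across sets.  Functional trajectories summarize a gene
set's members as per-sample mean z-scores within one tissue, with per-day
box summaries and pairwise day-vs-day t-tests annotated with significance
tiers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from tempro.differential import bh_adjust, student_t

logger = logging.getLogger(__name__)

STAR_TIERS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for cut, stars in STAR_TIERS:
        if p < cut:
            return stars
    return "ns"


def hypergeometric_enrichment(
    query: set[str] | list[str],
    collection: dict[str, set[str]],
    background: set[str] | list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each set in the query.

    p = P(overlap ≥ observed) drawing |query| genes from |background| of which
    |set ∩ background| are successes.  BH adjustment across sets.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise ValueError("empty query set")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    rows = []
    for name, genes in collection.items():
        genes_bg = set(genes) & background
        if not genes_bg:
            continue
        overlap = len(query & genes_bg)
        p = float(hypergeom.sf(overlap - 1, len(background), len(genes_bg), len(query)))
        rows.append({"set": name, "overlap": overlap, "set_size": len(genes_bg),
                     "query_size": len(query), "background_size": len(background),
                     "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = bh_adjust(out["p_value"].clip(lower=np.nextafter(0, 1)))
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out


@dataclass
class TrajectoryResult:
    """Per-sample and per-day summary of a function's mean z-score."""

    name: str
    direction: str                 # "up" | "down" | "all"
    per_sample: pd.Series          # mean z over member genes, per sample
    per_day: pd.DataFrame          # median/q1/q3/n per day
    pairwise: pd.DataFrame         # day_a, day_b, p_value, stars
    n_genes: int = 0


def function_zscore_trajectory(
    values: pd.DataFrame,
    gene_set: set[str] | list[str],
    design: pd.DataFrame,
    tissue: str,
    name: str = "function",
    direction: str = "all",
) -> TrajectoryResult:
    """Mean member-gene z-score per sample of one tissue, with day summaries.

    Each member gene is z-scored across all samples of the tissue (sample sd);
    zero-variance genes are dropped with a warning; the per-sample score is
    the mean over remaining members.  Pairwise day comparisons use the same
    two-sided Student's t as the differential stage.
    """
    sub = design[design["tissue"] == tissue]
    ids = [s for s in values.columns if s in set(sub["sample_id"])]
    if len(ids) < 2:
        raise ValueError("need >= 2 samples in the tissue")
    members = [g for g in gene_set if g in values.index]
    if not members:
        raise ValueError("gene set does not intersect the detected genes")
    X = values.loc[members, ids]
    sd = X.std(axis=1, ddof=1)
    if (sd == 0).any():
        logger.warning("dropping %d zero-variance genes from set %r",
                       int((sd == 0).sum()), name)
    X = X.loc[sd > 0]
    if X.empty:
        raise ValueError("all member genes are constant")
    Z = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=1), axis=0)
    per_sample = Z.mean(axis=0)

    days = sub.set_index("sample_id").loc[ids, "day"]
    summaries = []
    for d in sorted(days.unique()):
        v = per_sample[days[days == d].index]
        summaries.append({"day": d, "median": float(v.median()),
                          "q1": float(v.quantile(0.25)), "q3": float(v.quantile(0.75)),
                          "n": int(len(v))})
    pair_rows = []
    for da, db in itertools.combinations(sorted(days.unique()), 2):
        va = per_sample[days[days == da].index]
        vb = per_sample[days[days == db].index]
        if len(va) >= 2 and len(vb) >= 2:
            p = student_t(va, vb)
            pair_rows.append({"day_a": da, "day_b": db, "p_value": p,
                              "stars": significance_stars(p)})
    return TrajectoryResult(
        name=name,
        direction=direction,
        per_sample=per_sample,
        per_day=pd.DataFrame(summaries).set_index("day"),
        pairwise=pd.DataFrame(pair_rows),
        n_genes=len(Z),
    )


def assemble_dep_function_sets(
    de_results: dict[str, pd.DataFrame],
    collection: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
) -> list[tuple[str, str, set[str]]]:
    """Functions enriched in the union of up- (or down-) regulated proteins.

    For each direction, pools the DEPs of every day-vs-baseline contrast,
    tests each gene set against the detected-proteome background, and emits
    (function, direction, member genes among the pooled DEPs) for every set
    with adjusted p < alpha.  A function enriched both ways appears twice
    with distinct direction tags.
    """
    out: list[tuple[str, str, set[str]]] = []
    for direction in ("up", "down"):
        pooled: set[str] = set()
        for table in de_results.values():
            pooled |= set(table.index[table["call"] == direction])
        pooled &= background
        if not pooled:
            continue
        enr = hypergeometric_enrichment(pooled, collection, background)
        for row in enr.itertuples():
            if row.adj_p < alpha:
                members = set(collection[row.set]) & pooled
                out.append((row.set, direction, members))
    return out
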