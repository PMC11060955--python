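"""Fuzzy c-means clustering of temporal profiles and phase grouping.

Row-standardized (z-score) temporal profiles are soft-clustered with fuzzy
c-means: membership u_ij ∝ d_ij^(−2/(m−1)) and centers are u^m-weighted
means, iterated until the objective Σ u^m d² stabilizes.  The fuzzifier m
controls softness (m → 1 recovers k-means); when the user does not fix it,
it is estimated from the matrix dimensions with the Schwämmle–Jensen
heuristic.  Sample timepoints are grouped into developmental phases by
average-linkage hierarchical clustering on Spearman correlation distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)


def standardize_rows(values: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score each row (sample sd); zero-variance rows are dropped with a warning."""
    sd = values.std(axis=1, ddof=ddof)
    constant = sd == 0
    if constant.all():
        raise ValueError("all rows are constant; nothing to standardize")
    if constant.any():
        logger.warning("dropping %d constant rows before z-scoring", int(constant.sum()))
    v = values.loc[~constant]
    return v.sub(v.mean(axis=1), axis=0).div(sd[~constant], axis=0)


def estimate_fuzzifier(n_rows: int, n_cols: int, floor: float = 1.1) -> float:
    """Dimension-based fuzzifier heuristic (Schwämmle–Jensen), floored at 1.1."""
    if n_rows < 2 or n_cols < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    N, D = float(n_rows), float(n_cols)
    m = 1.0 + (1418.0 / N + 22.05) * D ** -2.0 \
        + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)
    return float(max(m, floor))


@dataclass
class FuzzyClustering:
    """Soft partition of temporal profiles.

    ``centers`` is k × timepoint (standardized units); ``membership`` rows are
    stochastic; ``hard_labels`` is the argmax assignment; ``objective`` the
    per-iteration weighted within-cluster distance (non-increasing).
    """

    k: int
    m: float
    centers: pd.DataFrame
    membership: pd.DataFrame
    hard_labels: pd.Series
    objective: list[float] = field(default_factory=list)


def _fcm_once(X: np.ndarray, k: int, m: float, tol: float, max_iter: int,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, list[float]]:
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    obj_hist: list[float] = []
    U = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        d2 = cdist(X, centers, metric="sqeuclidean")
        d2 = np.maximum(d2, 1e-12)
        w = d2 ** (-1.0 / (m - 1.0))
        U = w / w.sum(axis=1, keepdims=True)
        um = U ** m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        obj = float((um * cdist(X, centers, metric="sqeuclidean")).sum())
        obj_hist.append(obj)
        if len(obj_hist) > 1 and abs(obj_hist[-2] - obj) <= tol * max(obj_hist[-2], 1e-12):
            break
    return centers, U, obj_hist


def fuzzy_cmeans(
    values: pd.DataFrame,
    k: int,
    m: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 300,
    seed: int = 0,
    n_init: int = 5,
) -> FuzzyClustering:
    """Fuzzy c-means on row-standardized profiles (Euclidean distance).

    Runs ``n_init`` seeded restarts and keeps the solution with the lowest
    objective; deterministic given the seed.  ``m=None`` estimates the
    fuzzifier from the matrix dimensions.
    """
    X = values.to_numpy(dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of profiles ({n})")
    if m is None:
        m = estimate_fuzzifier(n, X.shape[1])
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if k == 1:
        centers = X.mean(axis=0, keepdims=True)
        U = np.ones((n, 1))
        obj = [float(((X - centers) ** 2).sum())]
    else:
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(n_init):
            cand = _fcm_once(X, k, m, tol, max_iter, rng)
            if best is None or cand[2][-1] < best[2][-1]:
                best = cand
        centers, U, obj = best
    tp = list(values.columns)
    names = [f"cluster_{i + 1}" for i in range(k)]
    return FuzzyClustering(
        k=k,
        m=float(m),
        centers=pd.DataFrame(centers, index=names, columns=tp),
        membership=pd.DataFrame(U, index=values.index, columns=names),
        hard_labels=pd.Series(U.argmax(axis=1), index=values.index, name="cluster"),
        objective=obj,
    )


def average_by_timepoint(
    values: pd.DataFrame, design: pd.DataFrame, tissue: str,
    exclude_day0: bool = True,
) -> pd.DataFrame:
    """Per-day replicate means for one tissue, optionally excluding the first day.

    The pre-implantation baseline differs so profoundly from the growing
    tumor that keeping it compresses the later dynamics; excluding it gives
    better resolution across the time course.
    """
    sub = design[design["tissue"] == tissue]
    days = sorted(sub["day"].unique())
    if exclude_day0:
        days = [d for d in days if d != min(days)]
    cols = {}
    for d in days:
        ids = sub.loc[sub["day"] == d, "sample_id"].tolist()
        cols[f"D{d}"] = values[ids].mean(axis=1)
    return pd.DataFrame(cols)


def group_timepoints(
    values: pd.DataFrame, design: pd.DataFrame, n_phases: int,
    tissue: str | None = None,
) -> dict[int, int]:
    """Group days into developmental phases.

    Samples are clustered by average linkage on 1 − Spearman ρ and the tree is
    cut into ``n_phases`` groups; each day takes the majority phase of its
    replicates.  Phases are renumbered 1..n in day order.
    """
    d = design if tissue is None else design[design["tissue"] == tissue]
    ids = [s for s in values.columns if s in set(d["sample_id"])]
    days = d.set_index("sample_id").loc[ids, "day"]
    n_days = days.nunique()
    if n_days < 2:
        raise ValueError("need >= 2 timepoints")
    if n_phases > n_days:
        raise ValueError(f"n_phases={n_phases} exceeds number of days ({n_days})")
    rho = spearmanr(values[ids].to_numpy()).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=n_phases, criterion="maxclust")
    phase_of_day: dict[int, int] = {}
    for day in sorted(days.unique()):
        members = labels[np.asarray(days == day)]
        vals, counts = np.unique(members, return_counts=True)
        phase_of_day[int(day)] = int(vals[counts.argmax()])
    # renumber phases in chronological order of first appearance
    remap: dict[int, int] = {}
    for day in sorted(phase_of_day):
        remap.setdefault(phase_of_day[day], len(remap) + 1)
    return {day: remap[p] for day, p in phase_of_day.items()}
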