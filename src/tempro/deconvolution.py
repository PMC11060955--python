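"""Signature-based immune-cell deconvolution with a permutation null.

Each sample (a bulk proteome restricted to signature genes) is modeled as a
non-negative combination of reference cell-type profiles.  Mixture and
signature columns are z-scored, the standardized mixture is fit by
non-negative least squares on the standardized signature columns, and the
coefficients are mapped back to the original scale (divide by each column's
sd) before sum-to-one normalization — with exact data this recovers the true
fractions exactly.  Significance of the fit is an empirical p-value from
permuting the mixture's gene labels.

Caveat surfaced as a warning: feeding proteomic mixtures to an RNA-derived
signature assumes RNA and protein levels rank cell types similarly, which is
only approximately true.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)


def validate_signature(signature: pd.DataFrame) -> None:
    if signature.shape[1] < 2:
        raise ValueError("signature needs >= 2 cell types")
    if (signature.to_numpy() < 0).any():
        raise ValueError("signature must be non-negative")
    if (signature.sum(axis=1) == 0).any():
        raise ValueError("signature contains all-zero gene rows")
    if np.linalg.matrix_rank(signature.to_numpy()) < signature.shape[1]:
        raise ValueError("signature columns are rank-deficient (duplicated cell types?)")


def _zscore(v: np.ndarray) -> tuple[np.ndarray, float]:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance vector cannot be standardized")
    return (v - v.mean()) / sd, sd


def deconvolve(sample: pd.Series, signature: pd.DataFrame) -> tuple[pd.Series, float]:
    """Estimate cell-type fractions of one sample.

    Returns (fractions summing to 1, rmse of the standardized reconstruction).
    Only genes shared between the sample and the signature are used; fewer
    than two shared genes is an error.
    """
    validate_signature(signature)
    shared = signature.index.intersection(sample.index)
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes overlap the signature")
    S = signature.loc[shared].to_numpy(dtype=float)
    y = sample.loc[shared].to_numpy(dtype=float)
    yz, _ = _zscore(y)
    cols, sds = [], []
    for j in range(S.shape[1]):
        z, sd = _zscore(S[:, j])
        cols.append(z)
        sds.append(sd)
    Sz = np.column_stack(cols)
    coef, resid = nnls(Sz, yz)
    rmse = float(resid / np.sqrt(len(shared)))
    raw = coef / np.asarray(sds)  # back to original scale
    total = raw.sum()
    if total == 0:
        logger.warning("all-zero NNLS fit; returning uniform fractions")
        fractions = np.full(S.shape[1], 1.0 / S.shape[1])
    else:
        fractions = raw / total
    return pd.Series(fractions, index=signature.columns, name=sample.name), rmse


def _fit_correlation(y: np.ndarray, Sz: np.ndarray) -> float:
    coef, _ = nnls(Sz, y)
    recon = Sz @ coef
    if recon.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(recon, y)[0, 1])


def permutation_p(
    sample: pd.Series,
    signature: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical p: fraction of gene-label permutations fitting at least as well.

    The statistic is the Pearson correlation between the NNLS reconstruction
    and the (standardized) mixture; p = (1 + #{null ≥ observed}) / (P + 1).
    """
    if n_permutations < 1:
        raise ValueError("need n_permutations >= 1")
    validate_signature(signature)
    shared = signature.index.intersection(sample.index)
    S = signature.loc[shared].to_numpy(dtype=float)
    y = sample.loc[shared].to_numpy(dtype=float)
    yz, _ = _zscore(y)
    Sz = np.column_stack([_zscore(S[:, j])[0] for j in range(S.shape[1])])
    observed = _fit_correlation(yz, Sz)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        exceed += _fit_correlation(rng.permutation(yz), Sz) >= observed
    return (1 + exceed) / (n_permutations + 1)


@dataclass
class DeconvolutionResult:
    """Per-sample fractions, fit residuals, and permutation p-values."""

    fractions: pd.DataFrame     # sample × cell type, rows sum to 1
    rmse: pd.Series
    perm_p: pd.Series
    n_permutations: int


def deconvolve_matrix(
    values: pd.DataFrame,
    signature: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
) -> DeconvolutionResult:
    """Deconvolve every sample column of an expression matrix.

    Quantile normalization is not applied (disabled for proteomic mixtures).
    """
    logger.warning(
        "deconvolving proteomic mixtures against an RNA-style signature; "
        "RNA and protein abundances correlate imperfectly"
    )
    fracs, rmses, ps = {}, {}, {}
    for i, col in enumerate(values.columns):
        f, r = deconvolve(values[col], signature)
        fracs[col] = f
        rmses[col] = r
        ps[col] = permutation_p(
            values[col], signature, n_permutations, seed=(seed * 7919 + i) % (2**31 - 1)
        )
    return DeconvolutionResult(
        fractions=pd.DataFrame(fracs).T,
        rmse=pd.Series(rmses, name="rmse"),
        perm_p=pd.Series(ps, name="perm_p"),
        n_permutations=n_permutations,
    )


def trajectory_summary(
    fractions: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean fraction per cell type per day, with per-day sample counts."""
    meta = design.set_index("sample_id")
    days = meta.loc[fractions.index, "day"]
    means = fractions.groupby(days).mean().T
    means.columns = [f"D{d}" for d in means.columns]
    counts = days.value_counts().sort_index()
    counts.index = [f"D{d}" for d in counts.index]
    return means, counts.rename("n_samples")
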