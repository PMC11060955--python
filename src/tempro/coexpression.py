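"""Weighted co-expression network modules and tissue-specificity calls.

The standard weighted-network workflow: a soft threshold β turns |Pearson
correlation| into adjacency |cor|^β (chosen as the smallest power giving an
approximately scale-free connectivity distribution), the topological overlap
measure (TOM) folds in shared neighborhoods, average-linkage clustering of
1 − TOM with a size-constrained tree cut yields modules, each summarized by
its eigengene (first principal component of the standardized module
submatrix).  Modules are related to tissues by correlating eigengenes with
tissue indicator traits; a gene is called tissue-specific when it is both
unique to one tissue's detected proteome (Venn rule) and a member of that
tissue's associated module.

Correlations are computed on log10(x + 0.1)-transformed abundances: iFOT
values are heavy-tailed and the pseudo-count keeps zeros finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

LOG_PSEUDO = 0.1
GREY = 0  # label for unassigned genes


def log_transform(values: pd.DataFrame) -> pd.DataFrame:
    return np.log10(values + LOG_PSEUDO)


def adjacency_matrix(values: pd.DataFrame, power: int) -> np.ndarray:
    """Unsigned adjacency |cor|^β with zero diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    X = values.to_numpy(dtype=float)
    cor = np.corrcoef(X)
    cor = np.nan_to_num(cor, nan=0.0)
    A = np.abs(cor) ** power
    np.fill_diagonal(A, 0.0)
    return A


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R² of log10 freq(k) vs log10 k over binned connectivity.

    A scale-free network shows a straight line with negative slope; fits with
    positive slope score 0.
    """
    k = connectivity[connectivity > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return 0.0
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, len(edges) - 2)
    kmean = np.array([k[idx == b].mean() for b in range(len(edges) - 1) if (idx == b).any()])
    freq = np.array([(idx == b).mean() for b in range(len(edges) - 1) if (idx == b).any()])
    x, y = np.log10(kmean), np.log10(freq)
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        return 0.0
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    return float(1.0 - resid @ resid / ss_tot) if ss_tot > 0 else 0.0


def pick_soft_threshold(
    values: pd.DataFrame,
    powers=tuple(range(1, 13)),
    r2_target: float = 0.8,
) -> tuple[int, pd.Series]:
    """Smallest power whose connectivity distribution fits scale-free R² ≥ target.

    Falls back to the power maximizing R² when no candidate reaches the
    target.  Returns the chosen β and the R² per candidate power.
    """
    if len(values) < 20:
        raise ValueError("need >= 20 genes to assess scale-free fit")
    fits = {}
    for p in powers:
        A = adjacency_matrix(values, p)
        fits[p] = scale_free_fit(A.sum(axis=1))
    fits = pd.Series(fits, name="r2")
    ok = fits[fits >= r2_target]
    beta = int(ok.index.min()) if len(ok) else int(fits.idxmax())
    return beta, fits


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij); TOM_ii = 1."""
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or not np.allclose(A, A.T):
        raise ValueError("adjacency must be square and symmetric")
    if (A < 0).any() or (A > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = A.sum(axis=1)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class CoexpressionModules:
    """Result of module detection on one expression matrix."""

    soft_power: int
    labels: pd.Series                      # gene -> module id (0 = unassigned)
    eigengenes: pd.DataFrame               # module × sample
    scale_free_fit: pd.Series              # R² per candidate power
    trait_correlations: pd.DataFrame | None = None
    min_module_size: int = 50
    merge_cut_height: float = 0.3

    def module_genes(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def module_eigengene(values: pd.DataFrame) -> pd.Series:
    """First principal component of a module's row-standardized submatrix.

    Unit norm over samples, sign-oriented to correlate positively with the
    module's mean standardized profile.
    """
    if len(values) < 2:
        raise ValueError("module needs >= 2 genes")
    sd = values.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise ValueError("module has no variance")
    Z = values.loc[sd > 0]
    Z = Z.sub(Z.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    _, _, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    e = vt[0]
    mean_profile = Z.mean(axis=0).to_numpy()
    if e @ mean_profile < 0:
        e = -e
    return pd.Series(e, index=values.columns, name="eigengene")


def _initial_clusters(dissim: np.ndarray, min_module_size: int) -> np.ndarray:
    """Static tree cut at the height yielding the most size-qualified clusters.

    Scans all merge heights of the average-linkage dendrogram and keeps the
    finest cut maximizing the number of clusters of size ≥ min_module_size —
    a simplified, deterministic stand-in for the dynamic tree cut.
    """
    n = dissim.shape[0]
    Z = linkage(squareform(dissim, checks=False), method="average")
    heights = np.unique(Z[:, 2])
    cuts = np.concatenate([[0.0], (heights[:-1] + heights[1:]) / 2.0, [heights[-1] + 1.0]])
    best_labels, best_score, best_cut = np.ones(n, dtype=int), 0, None
    for h in cuts:
        labels = cut_tree(Z, height=h).ravel()
        sizes = np.bincount(labels)
        score = int((sizes >= min_module_size).sum())
        if score > best_score:
            best_labels, best_score, best_cut = labels, score, h
    if best_score == 0:
        return np.zeros(n, dtype=int)  # no cluster large enough: all grey
    return best_labels


def detect_modules(
    values: pd.DataFrame,
    powers=tuple(range(1, 13)),
    r2_target: float = 0.8,
    min_module_size: int = 50,
    merge_cut_height: float = 0.3,
    absorb_cor: float = 0.3,
    log_input: bool = True,
) -> CoexpressionModules:
    """End-to-end module detection from an expression matrix.

    Pipeline: log transform → soft threshold → adjacency → TOM → average
    linkage on 1 − TOM → size-constrained tree cut → absorb small clusters
    into the best-correlated module (|eigengene cor| ≥ ``absorb_cor``, else
    unassigned) → iteratively merge modules whose eigengene dissimilarity
    1 − cor is below ``merge_cut_height``.
    """
    X = log_transform(values) if log_input else values
    beta, fits = pick_soft_threshold(X, powers, r2_target)
    A = adjacency_matrix(X, beta)
    tom = topological_overlap(A)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    raw = _initial_clusters(dissim, min_module_size)

    genes = X.index
    sizes = pd.Series(raw).value_counts()
    big = [c for c in sizes.index if sizes[c] >= min_module_size]
    labels = pd.Series(GREY, index=genes, name="module", dtype=int)
    for new_id, c in enumerate(sorted(big), start=1):
        labels[raw == c] = new_id

    eig = {
        mod: module_eigengene(X.loc[labels == mod])
        for mod in sorted(set(labels) - {GREY})
    }

    # absorb small clusters / leftover genes into correlated modules
    if eig:
        small = [c for c in sizes.index if sizes[c] < min_module_size]
        for c in small:
            members = genes[raw == c]
            profile = module_eigengene(X.loc[members]) if len(members) >= 2 else (
                (X.loc[members].iloc[0] - X.loc[members].iloc[0].mean())
                / X.loc[members].iloc[0].std(ddof=1)
                if X.loc[members].iloc[0].std(ddof=1) > 0 else None
            )
            if profile is None:
                continue
            cors = {mod: float(np.corrcoef(profile, e)[0, 1]) for mod, e in eig.items()}
            best = max(cors, key=lambda mod: abs(cors[mod]))
            if abs(cors[best]) >= absorb_cor:
                labels[members] = best
        eig = {
            mod: module_eigengene(X.loc[labels == mod])
            for mod in sorted(set(labels) - {GREY})
        }

    # merge modules with near-identical eigengenes
    while len(eig) > 1:
        mods = sorted(eig)
        best_pair, best_d = None, None
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                d = 1.0 - float(np.corrcoef(eig[a], eig[b])[0, 1])
                if best_d is None or d < best_d:
                    best_pair, best_d = (a, b), d
        if best_d is None or best_d >= merge_cut_height:
            break
        a, b = best_pair
        labels[labels == b] = a
        eig = {
            mod: module_eigengene(X.loc[labels == mod])
            for mod in sorted(set(labels) - {GREY})
        }

    # renumber modules densely by size
    final = pd.Series(GREY, index=genes, name="module", dtype=int)
    order = labels[labels != GREY].value_counts().index
    for new_id, mod in enumerate(order, start=1):
        final[labels == mod] = new_id
    eigengenes = pd.DataFrame(
        {mod: module_eigengene(X.loc[final == mod]) for mod in sorted(set(final) - {GREY})}
    ).T
    eigengenes.index.name = "module"
    return CoexpressionModules(
        soft_power=beta,
        labels=final,
        eigengenes=eigengenes,
        scale_free_fit=fits,
        min_module_size=min_module_size,
        merge_cut_height=merge_cut_height,
    )


def module_trait_association(
    modules: CoexpressionModules,
    design: pd.DataFrame,
    values: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Correlate module eigengenes with 0/1 tissue indicator traits.

    Returns module × tissue Pearson correlations, stored on the modules
    object.  When ``values`` is given, per-gene module membership (MM,
    correlation with the own-module eigengene) is appended as a column of
    ``modules.labels``' frame — callers needing GS/MM use
    :func:`gene_significance`.
    """
    tissues = sorted(design["tissue"].unique())
    if len(tissues) < 2:
        raise ValueError("trait association needs >= 2 tissues")
    sample_order = list(modules.eigengenes.columns)
    meta = design.set_index("sample_id").loc[sample_order]
    rows = {}
    for mod in modules.eigengenes.index:
        e = modules.eigengenes.loc[mod].to_numpy(dtype=float)
        rows[mod] = {
            t: float(np.corrcoef(e, (meta["tissue"] == t).astype(float))[0, 1])
            for t in tissues
        }
    out = pd.DataFrame(rows).T
    out.index.name = "module"
    modules.trait_correlations = out
    return out


def gene_significance(values: pd.DataFrame, design: pd.DataFrame,
                      tissue: str) -> pd.Series:
    """GS: |Pearson correlation| of each gene with a tissue's 0/1 indicator."""
    X = log_transform(values)
    ind = (design.set_index("sample_id").loc[X.columns, "tissue"] == tissue).astype(float)
    gs = X.apply(lambda row: abs(float(np.corrcoef(row, ind)[0, 1])), axis=1)
    return gs.rename(f"GS_{tissue}")


def tissue_associated_modules(
    trait_correlations: pd.DataFrame, threshold: float = 0.6
) -> dict[str, list[int]]:
    """Tissue -> modules whose top trait correlation is that tissue and ≥ threshold."""
    out: dict[str, list[int]] = {t: [] for t in trait_correlations.columns}
    for mod, row in trait_correlations.iterrows():
        best = row.idxmax()
        if row[best] >= threshold:
            out[best].append(int(mod))
    return out


def tissue_specific_intersection(
    tissue_tier3: dict[str, list[str]],
    modules: CoexpressionModules,
    trait_correlations: pd.DataFrame,
    threshold: float = 0.6,
) -> pd.DataFrame:
    """Tissue-specific proteins: Venn-unique AND member of the tissue's module.

    Venn-unique means detected in exactly one tissue's analysis-grade set;
    module membership uses the tissue-associated modules from the trait
    correlations.
    """
    assoc = tissue_associated_modules(trait_correlations, threshold)
    counts: dict[str, int] = {}
    for glist in tissue_tier3.values():
        for g in glist:
            counts[g] = counts.get(g, 0) + 1
    rows = []
    for tissue, glist in tissue_tier3.items():
        mod_genes = set()
        for mod in assoc.get(tissue, []):
            mod_genes.update(modules.module_genes(mod))
        for g in glist:
            venn = counts[g] == 1
            member = g in mod_genes
            rows.append({"gene": g, "tissue": tissue, "venn_unique": venn,
                         "module_member": member,
                         "tissue_specific": venn and member})
    return pd.DataFrame(rows)
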