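"""Synthetic study generator with planted ground truth.

Emulates the inputs of a tumor + immune-organ time-course proteomics study:
peptide-evidence tables whose genes are planted into the three confidence
tiers, log-normal expression matrices carrying temporal archetype patterns
and tissue-unique proteins, cell-type signature matrices, and mixtures with
known cell-type fractions.  Every generated entity is recorded in a
:class:`GroundTruth` object so each analysis stage can be scored exactly.

All generation is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tempro.config import SimulationConfig
from tempro.matrix import ExpressionMatrix, SampleMeta, design_frame

AMINO_ACIDS = "ACDEFGHILMNPQSTVWY"  # K/R reserved for tryptic termini
PSEUDO = 0.1


@dataclass
class GroundTruth:
    """Planted truth for a simulated study.

    Attributes
    ----------
    cluster
        gene -> planted temporal archetype id (0-based).
    tissue_label
        gene -> tissue name if planted tissue-unique, else ``"shared"``.
    tiers
        gene -> highest planted evidence tier (1, 2 or 3).
    differential
        contrast label -> {gene -> "up" | "down" | "ns"}, computed from the
        noiseless expected abundances with the pseudo-count fold-change rule.
    fractions
        sample_id -> true cell-type fraction vector (sums to 1).
    celltypes
        names aligning with the fraction vectors.
    """

    cluster: dict[str, int] = field(default_factory=dict)
    tissue_label: dict[str, str] = field(default_factory=dict)
    tiers: dict[str, int] = field(default_factory=dict)
    differential: dict[str, dict[str, str]] = field(default_factory=dict)
    fractions: dict[str, list[float]] = field(default_factory=dict)
    celltypes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Design

def generate_design(config: SimulationConfig) -> list[SampleMeta]:
    """One sample per tissue × day × replicate, in deterministic order."""
    config.validate()
    samples = []
    for tissue in config.tissues:
        for day in config.days:
            for rep in range(1, config.n_replicates + 1):
                samples.append(
                    SampleMeta(f"{tissue}_D{day}_R{rep}", tissue, int(day), rep)
                )
    return samples


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Expression

def simulate_expression(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a gene × sample abundance matrix with planted structure.

    Each gene carries a base log10 abundance, a per-tissue offset, and the
    temporal archetype of its planted cluster (in row-z units); Gaussian
    noise of sd ``intensity_log_sd`` is added on the log scale.  When
    archetypes exclude day 0, the first day carries no temporal term, mirroring
    a pre-implantation baseline.  Tissue-unique genes are exactly zero outside
    their tissue.  With zero noise, the row-standardized temporal profile of
    every gene equals its archetype exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = _gene_names(config.n_genes)
    design = design_frame(generate_design(config))
    arch = config.archetypes()
    arch_days = config.archetype_days

    k = config.n_temporal_clusters
    clusters = rng.permutation(np.arange(config.n_genes) % k)

    # Tissue-unique assignment: first blocks of a random permutation.
    labels = np.array(["shared"] * config.n_genes, dtype=object)
    n_unique_per_tissue = int(round(config.tissue_unique_fraction * config.n_genes))
    order = rng.permutation(config.n_genes)
    pos = 0
    for tissue in config.tissues:
        take = order[pos : pos + n_unique_per_tissue]
        labels[take] = tissue
        pos += n_unique_per_tissue
    if pos > config.n_genes:
        raise ValueError("tissue_unique_fraction too large for n_genes")

    base = rng.normal(1.0, 0.6, size=config.n_genes)
    toff = rng.normal(0.0, 0.3, size=(config.n_genes, config.n_tissues))
    tissue_idx = {t: i for i, t in enumerate(config.tissues)}
    day_term = {d: arch[:, j] for j, d in enumerate(arch_days)}

    vals = np.zeros((config.n_genes, len(design)))
    for j, row in enumerate(design.itertuples()):
        ti = tissue_idx[row.tissue]
        term = day_term.get(row.day, np.zeros(k))[clusters]
        eps = rng.normal(0.0, config.intensity_log_sd, size=config.n_genes)
        log10v = base + toff[:, ti] + term + eps
        col = 10.0 ** log10v
        col[(labels != "shared") & (labels != row.tissue)] = 0.0
        vals[:, j] = col

    values = pd.DataFrame(vals, index=genes, columns=design["sample_id"].tolist())
    gt = GroundTruth(
        cluster={g: int(c) for g, c in zip(genes, clusters)},
        tissue_label={g: str(l) for g, l in zip(genes, labels)},
        differential=_expected_differential(
            config, genes, clusters, labels, base, toff, day_term, tissue_idx
        ),
    )
    return ExpressionMatrix(values, design, provenance="synthetic"), gt


def _expected_differential(config, genes, clusters, labels, base, toff,
                           day_term, tissue_idx) -> dict[str, dict[str, str]]:
    """Noiseless expected fold-change calls for every day-vs-D0 contrast."""
    d0 = min(config.days)
    out: dict[str, dict[str, str]] = {}
    k = config.n_temporal_clusters
    zero = np.zeros(k)
    for tissue in config.tissues:
        ti = tissue_idx[tissue]
        e0 = 10.0 ** (base + toff[:, ti] + day_term.get(d0, zero)[clusters])
        e0[(labels != "shared") & (labels != tissue)] = 0.0
        for day in config.days:
            if day == d0:
                continue
            ed = 10.0 ** (base + toff[:, ti] + day_term.get(day, zero)[clusters])
            ed[(labels != "shared") & (labels != tissue)] = 0.0
            fc = (ed + PSEUDO) / (e0 + PSEUDO)
            call = np.where(fc >= 2.0, "up", np.where(fc <= 0.5, "down", "ns"))
            out[f"{tissue}:D{day} vs D0"] = dict(zip(genes, call))
    return out


# ---------------------------------------------------------------------------
# Peptide evidence

def _random_peptide(rng: np.random.Generator, used: set[str]) -> str:
    # no leading P: concatenated peptides must stay cleavable into themselves
    first_choices = AMINO_ACIDS.replace("P", "")
    while True:
        length = int(rng.integers(8, 18))
        first = str(rng.choice(list(first_choices)))
        body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 2))
        seq = first + body + ("K" if rng.random() < 0.5 else "R")
        if seq not in used:
            used.add(seq)
            return seq


def simulate_peptides(
    config: SimulationConfig,
    seed: int | None = None,
    abundance: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a peptide-evidence table with planted confidence tiers.

    Tier-1-only genes carry a single unique peptide with ion score in
    [20, 40) — strict, but failing every tier-2 clause.  Tier-2 and tier-3
    genes carry a unique peptide with score ≥ 41 plus shared low-score
    peptides.  Tier-2-only genes are then masked so that no (tissue, day)
    cell sees them in more than one replicate, while tier-3 genes are
    guaranteed non-zero in at least two replicates of one cell.  Intensities
    are log-normal with per-sample dropout.

    ``abundance`` optionally supplies per-gene, per-sample expected
    intensities (e.g. the matrix from :func:`simulate_expression`) so that
    quantifying the peptide table reproduces a planted expression structure;
    without it each gene gets a single log-normal abundance for all samples.
    With ``dropout_rate >= 1`` nothing is ever detected, so tier-3 cannot be
    planted and those genes are recorded as tier 2.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = _gene_names(config.n_genes)
    design = design_frame(generate_design(config))
    sample_ids = design["sample_id"].tolist()
    cells = {
        key: sub.index.to_numpy()
        for key, sub in design.groupby(["tissue", "day"], sort=True)
    }
    if abundance is not None:
        abundance = abundance.loc[genes, sample_ids]

    tiers = rng.permutation(np.arange(config.n_genes) % 3 + 1)
    total_dropout = config.dropout_rate >= 1.0
    used: set[str] = set()
    rows = []
    intensities = []
    for gi, gene in enumerate(genes):
        tier = int(tiers[gi])
        if abundance is None:
            base = np.full(len(sample_ids), 10.0 ** rng.normal(1.5, 0.7))
        else:
            base = abundance.iloc[gi].to_numpy(dtype=float)
        if tier == 1:
            peps = [(True, float(rng.uniform(20.0, 39.0)))]
        else:
            n_extra = int(rng.integers(1, 4))
            peps = [(True, float(rng.uniform(41.0, 90.0)))]
            peps += [(False, float(rng.uniform(5.0, 35.0))) for _ in range(n_extra)]
        shares = rng.dirichlet(np.ones(len(peps)) * 5.0)
        pep_inten = np.zeros((len(peps), len(sample_ids)))
        for pi in range(len(peps)):
            noise = 10.0 ** rng.normal(0.0, config.intensity_log_sd, size=len(sample_ids))
            pep_inten[pi] = base * shares[pi] * noise
        keep = rng.random(pep_inten.shape) >= config.dropout_rate
        pep_inten = np.where(keep, pep_inten, 0.0)

        if tier == 2:
            # at most one replicate detected per (tissue, day) cell
            for idx in cells.values():
                detected = [j for j in idx if pep_inten[:, j].sum() > 0]
                for j in detected[1:]:
                    pep_inten[:, j] = 0.0
        elif tier == 3 and not total_dropout:
            # guarantee >= 2 replicates in a cell where the gene is expressed
            for idx in cells.values():
                expressed = [j for j in idx if base[j] > 0]
                if len(expressed) >= 2:
                    for j in expressed[:2]:
                        if pep_inten[:, j].sum() == 0:
                            pep_inten[0, j] = base[j] * shares[0]
                    break
        elif tier == 3 and total_dropout:
            tiers[gi] = 2

        for pi, (is_unique, score) in enumerate(peps):
            rows.append(
                {
                    "accession": f"P{gi:04d}",
                    "gene": gene,
                    "sequence": _random_peptide(rng, used),
                    "ion_score": round(score, 3),
                    "is_unique": bool(is_unique),
                }
            )
            intensities.append(pep_inten[pi])

    evidence = pd.DataFrame(rows)
    inten = pd.DataFrame(np.vstack(intensities), columns=sample_ids)
    evidence = pd.concat([evidence, inten], axis=1)
    gt = GroundTruth(tiers={g: int(t) for g, t in zip(genes, tiers)})
    return evidence, gt


def protein_fasta_records(evidence: pd.DataFrame,
                          rng: np.random.Generator | None = None) -> dict[str, str]:
    """Build synthetic protein sequences consistent with an evidence table.

    Each accession's sequence is the concatenation of its observed peptides
    (every observed peptide ends in K/R, so each remains a tryptic product)
    plus a random tryptic tail, giving a positive theoretical peptide count.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    seqs: dict[str, str] = {}
    for acc, sub in evidence.groupby("accession", sort=True):
        tail_len = int(rng.integers(8, 15))
        tail = (
            str(rng.choice(list(AMINO_ACIDS.replace("P", ""))))
            + "".join(rng.choice(list(AMINO_ACIDS), size=tail_len - 2))
            + "K"
        )
        seqs[acc] = "".join(sub["sequence"]) + tail
    return seqs


# ---------------------------------------------------------------------------
# Signature matrices and mixtures

def simulate_signature(
    n_celltypes: int = 12,
    markers_per_type: int = 10,
    fold: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Marker-structured reference expression (genes × cell types).

    Each cell type receives ``markers_per_type`` marker genes expressed
    ``fold`` times above a shared log-normal background, the structure
    signature-based deconvolution relies on.
    """
    if n_celltypes < 2:
        raise ValueError("need >= 2 cell types")
    rng = np.random.default_rng(seed)
    n_genes = n_celltypes * markers_per_type
    genes = [f"M{i:04d}" for i in range(n_genes)]
    celltypes = [f"celltype_{i + 1}" for i in range(n_celltypes)]
    base = 10.0 ** rng.normal(0.5, 0.25, size=(n_genes, n_celltypes))
    for c in range(n_celltypes):
        rows = slice(c * markers_per_type, (c + 1) * markers_per_type)
        base[rows, c] *= fold
    return pd.DataFrame(base, index=genes, columns=celltypes)


def simulate_mixture(
    signature: pd.DataFrame,
    fractions,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mix signature columns with known fractions plus relative Gaussian noise.

    ``fractions`` is a vector (one mixture) or a (n_mixtures, n_celltypes)
    array; each row must be non-negative and sum to 1.  Noise is applied
    multiplicatively: value × (1 + N(0, noise_sd)), clipped at zero, so
    ``noise_sd`` is a relative error.
    """
    if signature.shape[1] < 2:
        raise ValueError("signature needs >= 2 cell types")
    F = np.atleast_2d(np.asarray(fractions, dtype=float))
    if F.shape[1] != signature.shape[1]:
        raise ValueError(
            f"fraction vectors have length {F.shape[1]}, "
            f"signature has {signature.shape[1]} cell types"
        )
    if (F < 0).any():
        raise ValueError("fractions must be non-negative")
    if not np.allclose(F.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("fraction vectors must sum to 1")
    rng = np.random.default_rng(seed)
    mix = signature.to_numpy() @ F.T
    if noise_sd > 0:
        mix = np.clip(mix * (1.0 + rng.normal(0.0, noise_sd, size=mix.shape)), 0.0, None)
    cols = [f"mix_{i + 1}" for i in range(F.shape[0])]
    return pd.DataFrame(mix, index=signature.index, columns=cols)


# ---------------------------------------------------------------------------
# Drug annotations

STATUSES = ("approved", "phase3", "phase1_2", "other")
CATEGORIES = ("driver", "cell_cycle", "apoptosis", "metabolic")


def simulate_drug_table(genes, druggable_fraction: float = 0.15,
                        seed: int = 0) -> pd.DataFrame:
    """Random drug-target annotations (stand-in for an external database).

    A fraction of genes is flagged druggable with a clinical status and zero
    or more functional categories.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    druggable = rng.random(len(genes)) < druggable_fraction
    rows = []
    for g, d in zip(genes, druggable):
        status = str(rng.choice(STATUSES, p=[0.25, 0.2, 0.4, 0.15])) if d else "other"
        cats = [c for c in CATEGORIES if d and rng.random() < 0.2]
        rows.append({"gene": g, "druggable": bool(d),
                     "status": status, "categories": ";".join(cats)})
    return pd.DataFrame(rows)
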