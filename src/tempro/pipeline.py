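"""End-to-end orchestration of the analysis stages.

``run_pipeline`` chains simulate → filter → quantify → de → cluster →
modules → deconv → enrich → targets, writing each stage's outputs as
plain-text files under one directory plus a manifest recording parameters,
seeds, and SHA-256 checksums.  Reruns with the same configuration reproduce
identical checksums: all randomness is derived from the root seed and floats
are serialized with fixed precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from tempro import io as tio
from tempro import synthetic
from tempro.config import PipelineConfig, SimulationConfig
from tempro.coexpression import (
    detect_modules,
    module_trait_association,
    tissue_specific_intersection,
)
from tempro.deconvolution import deconvolve_matrix, trajectory_summary
from tempro.differential import call_differential
from tempro.enrichment import assemble_dep_function_sets, function_zscore_trajectory
from tempro.identification import build_datasets, tier_gene_lists
from tempro.quantification import (
    collapse_to_gene,
    compute_ibaq,
    normalize_ifot,
    replicate_correlation,
)
from tempro.targets import prioritize_targets, summarize_candidates
from tempro.temporal_clustering import (
    average_by_timepoint,
    fuzzy_cmeans,
    group_timepoints,
    standardize_rows,
)

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(out: Path, stage: str, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = out / name
        if not p.exists():
            raise FileNotFoundError(f"stage {stage!r}: missing input file {p}")
        paths.append(p)
    return paths


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages in order; return (and write) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}

    for stage in config.stages:
        params = config.stage_params(stage)
        seed = config.stage_seed(stage)
        logger.info("stage %s (seed %d)", stage, seed)
        outputs = _STAGE_FUNCS[stage](config, params, seed, out)
        manifest["stages"].append(
            {
                "stage": stage,
                "params": {k: v for k, v in params.items()},
                "seed": seed,
                "outputs": {name: _sha256(out / name) for name in sorted(outputs)},
            }
        )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations.  Each returns the list of files it wrote.

def _stage_simulate(config: PipelineConfig, params: dict, seed: int, out: Path) -> list[str]:
    sim = config.simulation or SimulationConfig(n_genes=params["n_genes"], seed=seed)
    expr, gt = synthetic.simulate_expression(sim, seed=seed)
    evidence, gt_pep = synthetic.simulate_peptides(sim, seed=seed + 1, abundance=expr.values)
    gt.tiers = gt_pep.tiers
    rng = np.random.default_rng(seed + 2)
    seqs = synthetic.protein_fasta_records(evidence, rng)
    signature = synthetic.simulate_signature(sim.n_celltypes, seed=seed + 3)

    # mixtures: one per (day, replicate) of the tumor time course
    mix_design = expr.design[expr.design["tissue"] == "tumor"].reset_index(drop=True)
    fracs = rng.dirichlet(np.ones(sim.n_celltypes) * 1.5, size=len(mix_design))
    mixtures = synthetic.simulate_mixture(signature, fracs, noise_sd=0.05, seed=seed + 4)
    mixtures.columns = mix_design["sample_id"].tolist()
    gt.fractions = {s: list(map(float, f)) for s, f in zip(mixtures.columns, fracs)}
    gt.celltypes = list(signature.columns)

    # gene sets from the planted clusters; drug annotations with planted
    # tumor-unique genes flagged druggable so the target stage has real hits
    collection = {}
    for c in sorted(set(gt.cluster.values())):
        collection[f"planted_cluster_{c + 1}"] = {
            g for g, ci in gt.cluster.items() if ci == c
        }
    drug = synthetic.simulate_drug_table(expr.genes, seed=seed + 5)
    tumor_unique = [g for g, t in gt.tissue_label.items() if t == "tumor"]
    drug = drug.set_index("gene")
    drug.loc[tumor_unique, "druggable"] = True
    drug.loc[tumor_unique, "status"] = [
        synthetic.STATUSES[i % 3] for i in range(len(tumor_unique))
    ]
    drug = drug.reset_index()

    tio.write_evidence(evidence, out / "evidence.tsv")
    tio.write_design(expr.design, out / "design.tsv")
    tio.write_matrix(expr.values, out / "expression_true.tsv")
    tio.write_fasta(seqs, out / "proteins.fasta")
    tio.write_matrix(signature, out / "signature.tsv")
    tio.write_matrix(mixtures, out / "mixtures.tsv")
    tio.write_design(mix_design, out / "mixture_design.tsv")
    tio.write_gmt(collection, out / "gene_sets.gmt")
    tio.write_drug_table(drug, out / "drug_table.tsv")
    gt.to_json(out / "ground_truth.json")
    return [
        "evidence.tsv", "design.tsv", "expression_true.tsv", "proteins.fasta",
        "signature.tsv", "mixtures.tsv", "mixture_design.tsv", "gene_sets.gmt",
        "drug_table.tsv", "ground_truth.json",
    ]


def _stage_filter(config: PipelineConfig, params: dict, seed: int, out: Path) -> list[str]:
    ev_p, d_p = _require(out, "filter", "evidence.tsv", "design.tsv")
    evidence = tio.read_evidence(ev_p)
    design = tio.read_design(d_p)
    tiers, tissue_tier3 = build_datasets(evidence, design)
    tiers.to_csv(out / "tiers.tsv", sep="\t")
    (out / "tissue_tier3.json").write_text(json.dumps(tissue_tier3, indent=1, sort_keys=True))
    (out / "tier_lists.json").write_text(
        json.dumps({str(k): v for k, v in tier_gene_lists(tiers).items()},
                   indent=1, sort_keys=True)
    )
    return ["tiers.tsv", "tissue_tier3.json", "tier_lists.json"]


def _stage_quantify(config: PipelineConfig, params: dict, seed: int, out: Path) -> list[str]:
    ev_p, fa_p, d_p, t_p = _require(
        out, "quantify", "evidence.tsv", "proteins.fasta", "design.tsv", "tiers.tsv"
    )
    evidence = tio.read_evidence(ev_p)
    seqs = tio.read_fasta(fa_p)
    design = tio.read_design(d_p)
    tiers = pd.read_csv(t_p, sep="\t", index_col=0)
    sample_cols = design["sample_id"].tolist()
    ibaq = compute_ibaq(evidence, seqs, sample_cols,
                        params["min_len"], params["max_len"], params["missed_cleavages"])
    gene_ibaq = collapse_to_gene(ibaq, sample_cols)
    tier2 = tiers.index[tiers["tier2"]]
    tier3 = tiers.index[tiers["tier3"]]
    ifot = normalize_ifot(gene_ibaq.loc[gene_ibaq.index.intersection(tier2)])
    tio.write_matrix(ifot, out / "expression_ifot.tsv")
    tio.write_matrix(ifot.loc[ifot.index.intersection(tier3)], out / "expression_tier3.tsv")
    qc = replicate_correlation(ifot, design)
    qc.to_csv(out / "qc_replicate_correlation.tsv", sep="\t", index=False,
              float_format="%.6g")
    return ["expression_ifot.tsv", "expression_tier3.tsv", "qc_replicate_correlation.tsv"]


def _stage_de(config: PipelineConfig, params: dict, seed: int, out: Path) -> list[str]:
    e_p, d_p = _require(out, "de", "expression_tier3.tsv", "design.tsv")
    values = tio.read_matrix(e_p)
    design = tio.read_design(d_p)
    d0 = int(design["day"].min())
    tables = []
    for tissue in sorted(design["tissue"].unique()):
        for day in sorted(design["day"].unique()):
            if day == d0:
                continue
            tables.append(
                call_differential(
                    values, design, f"{tissue}:D{day} vs D{d0}",
                    fc_threshold=params["fc_threshold"], alpha=params["alpha"],
                    pseudo=params["pseudo"],
                )
            )
    de = pd.concat(tables)
    de.to_csv(out / "differential.tsv", sep="\t", float_format="%.6g",
              index_label="gene")
    if "tumor" in set(design["tissue"]):
        days = sorted(design["day"].unique())
        d3 = days[1]
        tenfold = call_differential(values, design, f"tumor:D{d3} vs D{d0}",
                                    fc_threshold=10.0, alpha=params["alpha"],
                                    pseudo=params["pseudo"])
        tenfold.to_csv(out / "differential_tumor_10fold.tsv", sep="\t",
                       float_format="%.6g", index_label="gene")
        return ["differential.tsv", "differential_tumor_10fold.tsv"]
    return ["differential.tsv"]


def _stage_cluster(config: PipelineConfig, params: dict, seed: int, out: Path) -> list[str]:
    e_p, d_p = _require(out, "cluster", "expression_tier3.tsv", "design.tsv")
    values = tio.read_matrix(e_p)
    design = tio.read_design(d_p)
    tissue = "tumor" if "tumor" in set(design["tissue"]) else sorted(design["tissue"])[0]
    prof = average_by_timepoint(np.log10(values + 0.1), design, tissue,
                                exclude_day0=params["exclude_day0"])
    z = standardize_rows(prof)
    fc = fuzzy_cmeans(z, k=params["k"], m=params["m"], seed=seed)
    tio.write_matrix(fc.centers, out / "cluster_centers.tsv", index_label="cluster")
    tio.write_matrix(fc.membership, out / "cluster_membership.tsv")
    fc.hard_labels.to_csv(out / "cluster_labels.tsv", sep="\t", index_label="gene")
    n_phases = min(4, design["day"].nunique())
    phases = group_timepoints(np.log10(values + 0.1), design, n_phases, tissue=tissue)
    (out / "phases.json").write_text(
        json.dumps({f"D{d}": p for d, p in phases.items()}, indent=1, sort_keys=True)
    )
    return ["cluster_centers.tsv", "cluster_membership.tsv", "cluster_labels.tsv",
            "phases.json"]


def _stage_modules(config: PipelineConfig, params: dict, seed: int, out: Path) -> list[str]:
    e_p, d_p, t_p = _require(out, "modules", "expression_tier3.tsv", "design.tsv",
                             "tissue_tier3.json")
    values = tio.read_matrix(e_p)
    design = tio.read_design(d_p)
    tissue_tier3 = json.loads(t_p.read_text())
    mods = detect_modules(values, r2_target=params["r2_target"],
                          min_module_size=params["min_module_size"],
                          merge_cut_height=params["merge_cut_height"])
    trait = module_trait_association(mods, design)
    calls = tissue_specific_intersection(tissue_tier3, mods, trait,
                                         threshold=params["trait_threshold"])
    mods.labels.to_csv(out / "module_labels.tsv", sep="\t", index_label="gene")
    tio.write_matrix(mods.eigengenes, out / "module_eigengenes.tsv", index_label="module")
    tio.write_matrix(trait, out / "module_trait_correlations.tsv", index_label="module")
    calls.to_csv(out / "tissue_specific.tsv", sep="\t", index=False)
    return ["module_labels.tsv", "module_eigengenes.tsv",
            "module_trait_correlations.tsv", "tissue_specific.tsv"]


def _stage_deconv(config: PipelineConfig, params: dict, seed: int, out: Path) -> list[str]:
    m_p, s_p, d_p = _require(out, "deconv", "mixtures.tsv", "signature.tsv",
                             "mixture_design.tsv")
    mixtures = tio.read_matrix(m_p)
    signature = tio.read_matrix(s_p)
    mix_design = tio.read_design(d_p)
    res = deconvolve_matrix(mixtures, signature,
                            n_permutations=params["n_permutations"], seed=seed)
    tio.write_matrix(res.fractions, out / "cell_fractions.tsv", index_label="sample_id")
    stats = pd.DataFrame({"rmse": res.rmse, "perm_p": res.perm_p})
    stats.to_csv(out / "deconv_stats.tsv", sep="\t", float_format="%.6g",
                 index_label="sample_id")
    means, counts = trajectory_summary(res.fractions, mix_design)
    tio.write_matrix(means, out / "cell_trajectories.tsv", index_label="celltype")
    return ["cell_fractions.tsv", "deconv_stats.tsv", "cell_trajectories.tsv"]


def _stage_enrich(config: PipelineConfig, params: dict, seed: int, out: Path) -> list[str]:
    de_p, g_p, e_p, d_p = _require(out, "enrich", "differential.tsv", "gene_sets.gmt",
                                   "expression_tier3.tsv", "design.tsv")
    de = pd.read_csv(de_p, sep="\t", index_col=0)
    collection = tio.read_gmt(g_p)
    values = tio.read_matrix(e_p)
    design = tio.read_design(d_p)
    background = set(values.index)
    de_by_contrast = {c: sub for c, sub in de.groupby("contrast")}
    sets = assemble_dep_function_sets(de_by_contrast, collection, background,
                                      alpha=params["alpha"])
    rows = [{"set": n, "direction": d, "n_genes": len(g),
             "genes": ";".join(sorted(g))} for n, d, g in sets]
    pd.DataFrame(rows, columns=["set", "direction", "n_genes", "genes"]).to_csv(
        out / "function_sets.tsv", sep="\t", index=False
    )
    written = ["function_sets.tsv"]
    if sets:
        name, direction, genes = sets[0]
        tissue = "tumor" if "tumor" in set(design["tissue"]) else sorted(design["tissue"])[0]
        traj = function_zscore_trajectory(values, genes, design, tissue,
                                          name=name, direction=direction)
        traj.per_day.to_csv(out / "trajectory_summary.tsv", sep="\t",
                            float_format="%.6g")
        traj.pairwise.to_csv(out / "trajectory_tests.tsv", sep="\t",
                             float_format="%.6g", index=False)
        written += ["trajectory_summary.tsv", "trajectory_tests.tsv"]
    return written


def _stage_targets(config: PipelineConfig, params: dict, seed: int, out: Path) -> list[str]:
    e_p, d_p, dr_p = _require(out, "targets", "expression_tier3.tsv", "design.tsv",
                              "drug_table.tsv")
    values = tio.read_matrix(e_p)
    design = tio.read_design(d_p)
    drug = tio.read_drug_table(dr_p)
    cand = prioritize_targets(values, design, drug,
                              alpha=params["alpha"], ratio=params["ratio"])
    cand.to_csv(out / "target_candidates.tsv", sep="\t", float_format="%.6g")
    summary: dict = {"n_selected": int(cand["selected"].sum())}
    if cand["selected"].any():
        s = summarize_candidates(cand)
        summary["categories"] = {
            k: {"count": int(r["count"]), "percent": float(r["percent"])}
            for k, r in s.iterrows()
        }
    (out / "target_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return ["target_candidates.tsv", "target_summary.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "quantify": _stage_quantify,
    "de": _stage_de,
    "cluster": _stage_cluster,
    "modules": _stage_modules,
    "deconv": _stage_deconv,
    "enrich": _stage_enrich,
    "targets": _stage_targets,
}
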