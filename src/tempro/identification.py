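"""Three-tier confidence filtering of peptide evidence.

Gene products are graded into nested datasets: tier 1 is every identification;
tier 2 requires convincing peptide evidence (a unique peptide with two strict
peptides, or three strict peptides, or one unique strict peptide with ion
score ≥ 40); tier 3 additionally requires detection in at least two replicates
of one (tissue, day) cell.  Tier 3 is the analysis-grade set.

A "strict" peptide has ion score ≥ 20; a "unique" peptide maps to exactly one
protein.  The evidence table is assumed pre-filtered to 1% peptide FDR by the
upstream search engine.
"""

from __future__ import annotations

import pandas as pd

STRICT_SCORE = 20.0
UNIQUE_STRICT_SCORE = 40.0
MIN_PEPTIDE_LENGTH = 7
MIN_REPLICATES_DETECTED = 2

EVIDENCE_COLUMNS = ["accession", "gene", "sequence", "ion_score", "is_unique"]


def validate_evidence(evidence: pd.DataFrame, design: pd.DataFrame) -> list[str]:
    """Check schema and invariants; return the ordered list of sample columns."""
    missing = [c for c in EVIDENCE_COLUMNS if c not in evidence.columns]
    if missing:
        raise ValueError(f"evidence table missing columns: {missing}")
    sample_cols = [c for c in evidence.columns if c not in EVIDENCE_COLUMNS]
    unknown = set(sample_cols) - set(design["sample_id"])
    if unknown:
        raise ValueError(f"evidence has sample columns absent from design: {sorted(unknown)}")
    if len(evidence) and (evidence["sequence"].str.len() < MIN_PEPTIDE_LENGTH).any():
        bad = evidence.loc[evidence["sequence"].str.len() < MIN_PEPTIDE_LENGTH, "sequence"]
        raise ValueError(f"peptides shorter than {MIN_PEPTIDE_LENGTH} aa: {list(bad.head())}")
    if len(evidence) and (evidence["ion_score"] < 0).any():
        raise ValueError("negative ion scores")
    return sample_cols


def is_strict(ion_score: float) -> bool:
    """Strict peptide: ion score of 20 or higher (boundary inclusive)."""
    return float(ion_score) >= STRICT_SCORE


def passes_tier2(peptides: pd.DataFrame) -> bool:
    """Tier-2 evidence rule for one gene's peptides.

    True iff (≥1 unique peptide AND ≥2 strict peptides) OR (≥3 strict
    peptides) OR (≥1 unique peptide with ion score ≥ 40).  A unique strict
    peptide counts toward both the unique and the strict tallies.
    """
    if len(peptides) == 0:
        raise ValueError("empty peptide list")
    strict = peptides["ion_score"] >= STRICT_SCORE
    unique = peptides["is_unique"].astype(bool)
    n_strict = int(strict.sum())
    if unique.any() and n_strict >= 2:
        return True
    if n_strict >= 3:
        return True
    return bool((unique & (peptides["ion_score"] >= UNIQUE_STRICT_SCORE)).any())


def passes_tier3(detected: pd.Series, design: pd.DataFrame,
                 min_replicates: int = MIN_REPLICATES_DETECTED) -> bool:
    """Tier-3 rule: detected in ≥ 2 replicates of at least one (tissue, day) cell.

    ``detected`` is a boolean Series indexed by sample_id.  The threshold stays
    at two whatever the replicate count of a cell (literal reading of
    "two of three").
    """
    d = design.set_index("sample_id")
    counts = detected[detected].index.to_series().map(
        lambda s: (d.loc[s, "tissue"], d.loc[s, "day"])
    )
    if counts.empty:
        return False
    return bool(counts.value_counts().max() >= min_replicates)


def build_datasets(
    evidence: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Grade every gene into the nested evidence tiers.

    Returns
    -------
    tiers
        DataFrame indexed by gene with boolean columns tier1/tier2/tier3
        (tier3 ⇒ tier2 ⇒ tier1).
    tissue_tier3
        Per-tissue lists of tier-3 genes detected (non-zero with
        tier-2-qualifying evidence, in ≥2 replicates of a day) within that
        tissue — the inputs of the tissue-uniqueness Venn analysis.
    """
    sample_cols = validate_evidence(evidence, design)
    if evidence.empty:
        tiers = pd.DataFrame(columns=["tier1", "tier2", "tier3"]).rename_axis("gene")
        return tiers, {t: [] for t in design["tissue"].unique()}

    records = []
    tissue_tier3: dict[str, list[str]] = {t: [] for t in design["tissue"].unique()}
    cell_of = {r.sample_id: (r.tissue, r.day) for r in design.itertuples()}
    for gene, sub in evidence.groupby("gene", sort=True):
        t2 = passes_tier2(sub)
        t3 = False
        if t2 and sample_cols:
            detected = (sub[sample_cols] > 0).any(axis=0)
            t3 = passes_tier3(detected, design)
            if t3:
                per_tissue: dict[str, dict] = {}
                for s in detected[detected].index:
                    tissue, day = cell_of[s]
                    per_tissue.setdefault(tissue, {}).setdefault(day, 0)
                    per_tissue[tissue][day] += 1
                for tissue, days in per_tissue.items():
                    if max(days.values()) >= MIN_REPLICATES_DETECTED:
                        tissue_tier3[tissue].append(gene)
        records.append({"gene": gene, "tier1": True, "tier2": t2, "tier3": t3})
    tiers = pd.DataFrame(records).set_index("gene")
    assert not (tiers["tier3"] & ~tiers["tier2"]).any()  # nesting invariant
    return tiers, {t: sorted(v) for t, v in tissue_tier3.items()}


def tier_gene_lists(tiers: pd.DataFrame) -> dict[int, list[str]]:
    """The three nested gene lists (DataSet 1 ⊇ 2 ⊇ 3)."""
    return {
        1: sorted(tiers.index[tiers["tier1"]]),
        2: sorted(tiers.index[tiers["tier2"]]),
        3: sorted(tiers.index[tiers["tier3"]]),
    }
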