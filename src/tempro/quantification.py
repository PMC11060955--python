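"""iBAQ/iFOT label-free quantification.

iBAQ divides a protein's summed peptide intensity by its number of
theoretically observable tryptic peptides, removing protein-length bias.
iFOT expresses iBAQ as a fraction of the per-sample total, × 1e5, making
columns comparable across runs.  Proteins are finally collapsed to the gene
level (sum over isoforms).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from pyteomics import parser as pyt_parser
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

IFOT_SCALE = 1e5
TRYPSIN_RULE = r"(?<=[KR])(?!P)"  # cleave C-terminal to K/R, not before P
VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


def count_theoretical_peptides(
    sequence: str,
    min_len: int = 7,
    max_len: int = 30,
    missed_cleavages: int = 0,
) -> int:
    """Number of distinct fully tryptic peptides with length in [min_len, max_len]."""
    if not sequence:
        raise ValueError("empty protein sequence")
    bad = set(sequence) - VALID_AA
    if bad:
        raise ValueError(f"invalid amino acids in sequence: {sorted(bad)}")
    peptides = pyt_parser.cleave(sequence, TRYPSIN_RULE, missed_cleavages=missed_cleavages)
    return sum(min_len <= len(p) <= max_len for p in peptides)


def compute_ibaq(
    evidence: pd.DataFrame,
    sequences: dict[str, str],
    sample_cols: list[str],
    min_len: int = 7,
    max_len: int = 30,
    missed_cleavages: int = 0,
) -> pd.DataFrame:
    """Per-protein iBAQ: summed peptide intensity / theoretical peptide count.

    Returns a DataFrame indexed by accession with a ``gene`` column, a
    ``n_theoretical`` column, and one iBAQ column per sample.  Proteins whose
    digest yields no peptide in the length window are dropped with a warning.
    """
    rows = []
    for acc, sub in evidence.groupby("accession", sort=True):
        if acc not in sequences:
            raise ValueError(f"no protein sequence for accession {acc!r}")
        n_theor = count_theoretical_peptides(
            sequences[acc], min_len, max_len, missed_cleavages
        )
        if n_theor == 0:
            logger.warning("accession %s has no theoretical peptides; dropped", acc)
            continue
        raw = sub[sample_cols].sum(axis=0)
        rows.append(
            pd.concat(
                [pd.Series({"gene": sub["gene"].iloc[0], "n_theoretical": n_theor}),
                 raw / n_theor]
            ).rename(acc)
        )
    if not rows:
        raise ValueError("no quantifiable proteins")
    out = pd.DataFrame(rows)
    out.index.name = "accession"
    return out


def normalize_ifot(ibaq: pd.DataFrame, scale: float = IFOT_SCALE) -> pd.DataFrame:
    """Column-normalize iBAQ to fractions of total × scale (default 1e5)."""
    totals = ibaq.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample columns: {list(zero.index)}")
    return ibaq / totals * scale


def collapse_to_gene(protein_quant: pd.DataFrame, sample_cols: list[str]) -> pd.DataFrame:
    """Sum protein-level values per gene symbol (isoform collapse)."""
    if protein_quant["gene"].isna().any() or (protein_quant["gene"] == "").any():
        missing = protein_quant.index[
            protein_quant["gene"].isna() | (protein_quant["gene"] == "")
        ]
        raise ValueError(f"missing gene symbol for accessions: {list(missing)}")
    out = protein_quant.groupby("gene", sort=True)[sample_cols].sum()
    out.index.name = "gene"
    return out


def replicate_correlation(
    values: pd.DataFrame, design: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """Rank correlation between replicate pairs within each (tissue, day) cell.

    Only genes detected (non-zero) in both members of a pair enter the
    correlation, matching how inter-experiment reproducibility is usually
    reported.
    """
    if method != "spearman":
        raise ValueError("only spearman supported")
    rows = []
    for (tissue, day), sub in design.groupby(["tissue", "day"], sort=True):
        ids = [s for s in sub["sample_id"] if s in values.columns]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = values[ids[i]], values[ids[j]]
                both = (a > 0) & (b > 0)
                rho = np.nan
                if both.sum() >= 2:
                    rho = float(spearmanr(a[both], b[both]).statistic)
                rows.append({"tissue": tissue, "day": day,
                             "sample_a": ids[i], "sample_b": ids[j],
                             "n_genes": int(both.sum()), "rho": rho})
    if not rows:
        raise ValueError("no replicate pairs in design")
    return pd.DataFrame(rows)
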