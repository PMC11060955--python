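"""Core containers: sample metadata and the gene × sample expression matrix.

The expression matrix is the currency of every downstream stage.  Values are
iFOT (intensity-based fraction of total × 1e5) or raw intensities depending on
provenance; rows are gene symbols, columns are sample ids, and a design table
maps sample ids to (tissue, day, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("tumor", "LN", "MLN", "spleen")


@dataclass(frozen=True)
class SampleMeta:
    """One sample of the design: a (tissue, day, replicate) cell."""

    sample_id: str
    tissue: str
    day: int
    replicate: int


def design_frame(samples: list[SampleMeta]) -> pd.DataFrame:
    """Tabulate sample metadata; enforces uniqueness of (tissue, day, replicate)."""
    df = pd.DataFrame(
        [(s.sample_id, s.tissue, s.day, s.replicate) for s in samples],
        columns=["sample_id", "tissue", "day", "replicate"],
    )
    if df.duplicated(["tissue", "day", "replicate"]).any():
        raise ValueError("duplicate (tissue, day, replicate) in design")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design")
    return df


@dataclass
class ExpressionMatrix:
    """Gene × sample abundance matrix with its design and provenance.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample_id.
        Non-negative.
    design
        DataFrame with columns sample_id, tissue, day, replicate, one row per
        column of ``values`` (same order not required; matched by sample_id).
    provenance
        Free-text tag recording which evidence tier / normalization produced
        the matrix (e.g. ``"ifot:tier3"``).
    """

    values: pd.DataFrame
    design: pd.DataFrame
    provenance: str = "raw"

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.design["sample_id"])
        if missing:
            raise ValueError(f"samples absent from design: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.design, self.provenance)

    def subset_samples(self, tissue: str | None = None, days=None) -> "ExpressionMatrix":
        """Restrict to samples of one tissue and/or a set of days."""
        d = self.design
        mask = pd.Series(True, index=d.index)
        if tissue is not None:
            mask &= d["tissue"] == tissue
        if days is not None:
            mask &= d["day"].isin(list(days))
        ids = [s for s in self.values.columns if s in set(d.loc[mask, "sample_id"])]
        return ExpressionMatrix(self.values[ids], d[mask].reset_index(drop=True), self.provenance)

    def sample_meta(self) -> dict[str, SampleMeta]:
        return {
            r.sample_id: SampleMeta(r.sample_id, r.tissue, int(r.day), int(r.replicate))
            for r in self.design.itertuples()
        }


def group_columns(design: pd.DataFrame, by=("tissue", "day")) -> dict[tuple, list[str]]:
    """Map each (tissue, day) cell (or other grouping) to its sample ids."""
    out: dict[tuple, list[str]] = {}
    for key, sub in design.groupby(list(by), sort=True):
        out[key if isinstance(key, tuple) else (key,)] = list(sub["sample_id"])
    return out


def check_column_sums(values: pd.DataFrame, total: float = 1e5, rtol: float = 1e-6) -> bool:
    sums = values.sum(axis=0).to_numpy(dtype=float)
    return bool(np.allclose(sums, total, rtol=rtol))
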