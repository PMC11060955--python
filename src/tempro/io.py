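"""Readers and writers for the pipeline's plain-text formats.

TSV for matrices, designs, evidence, and drug tables; GMT for gene-set
collections; FASTA (via Biopython) for protein sequences.  Floats are written
with 6 significant digits so that checksums of re-runs are stable.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tempro.quantification import VALID_AA

FLOAT_FORMAT = "%.6g"


# -- expression / generic matrices ------------------------------------------

def write_matrix(values: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][:3]
        raise ValueError(f"{path}: duplicated row names, e.g. {list(dup)}")
    return df


# -- design ------------------------------------------------------------------

DESIGN_COLUMNS = ["sample_id", "tissue", "day", "replicate"]


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: design missing columns {missing}")
    df["day"] = df["day"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    if df.duplicated(["tissue", "day", "replicate"]).any():
        raise ValueError(f"{path}: duplicate (tissue, day, replicate) rows")
    return df[DESIGN_COLUMNS]


# -- peptide evidence --------------------------------------------------------

def write_evidence(evidence: pd.DataFrame, path: str | Path) -> None:
    evidence.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=False)


def read_evidence(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("accession", "gene", "sequence", "ion_score", "is_unique"):
        if col not in df.columns:
            raise ValueError(f"{path}: evidence missing column {col!r}")
    df["is_unique"] = df["is_unique"].astype(bool)
    return df


# -- GMT gene sets -----------------------------------------------------------

def write_gmt(collection: dict[str, set[str] | list[str]], path: str | Path,
              source: str = "tempro") -> None:
    with open(path, "w") as fh:
        for name in collection:
            genes = sorted(collection[name])
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            fh.write("\t".join([name, source, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, source, >=1 gene")
            name, _, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in out:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            out[name] = set(genes)
    if not out:
        raise ValueError(f"{path}: no gene sets")
    return out


# -- FASTA -------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_AA
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} has non-amino-acid characters {sorted(bad)}"
            )
        out[rec.id] = seq
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


# -- drug annotations --------------------------------------------------------

def write_drug_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_drug_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "druggable", "status"):
        if col not in df.columns:
            raise ValueError(f"{path}: drug table missing column {col!r}")
    if "categories" not in df.columns:
        df["categories"] = ""
    df["categories"] = df["categories"].fillna("")
    df["druggable"] = df["druggable"].astype(bool)
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].head(3).tolist()
        raise ValueError(f"{path}: duplicated genes in drug table, e.g. {dup}")
    return df
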