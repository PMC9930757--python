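"""Readers and writers for the pipeline's tabular and sequence formats.

All tables are plain CSV with strict schema validation; 3'UTR sequences use
FASTA (one record per gene, header = gene symbol), read through Biopython
with optional DNA->RNA transliteration.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .are_screen import GeneRecord, transliterate

PathLike = Union[str, Path]

CT_COLUMNS = ["sample_id", "animal_id", "group", "gene", "replicate", "ct"]
QC_COLUMNS = ["sample_id", "od_ratio", "rin"]
DILUTION_COLUMNS = ["gene", "relative_concentration", "ct"]
GENE_META_COLUMNS = [
    "symbol", "accession", "subgroup", "are_status", "are_class", "are_score",
    "in_ared", "go_category", "log2fc", "adj_p", "efficiency", "is_reference",
]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s) {missing}")


def read_ct_csv(path: PathLike, group_vocabulary: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a long-format Ct table, validating schema and Ct range."""
    df = pd.read_csv(path)
    _require_columns(df, CT_COLUMNS, "Ct table")
    df["ct"] = pd.to_numeric(df["ct"])
    bad = df.index[(df["ct"] <= 0) | (df["ct"] >= 45)]
    if len(bad):
        raise ValueError(f"Ct values out of (0, 45) at row(s) {list(bad[:5])}")
    if group_vocabulary is not None:
        unknown = set(df["group"].astype(str)) - set(group_vocabulary)
        if unknown:
            raise ValueError(f"unknown group label(s) {sorted(unknown)}")
    return df[CT_COLUMNS + [c for c in df.columns if c not in CT_COLUMNS]]


def write_ct_csv(df: pd.DataFrame, path: PathLike) -> None:
    _require_columns(df, CT_COLUMNS, "Ct table")
    df.to_csv(path, index=False)


def read_qc_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, QC_COLUMNS, "sample QC table")
    return df


def read_dilution_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, DILUTION_COLUMNS, "dilution table")
    return df


def read_fasta(path: PathLike, to_rna: bool = True) -> dict[str, str]:
    """FASTA -> {gene symbol: sequence}; transliterates T->U by default."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        seqs[record.id] = transliterate(seq) if to_rna else seq.upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gene_metadata(path: PathLike) -> list[GeneRecord]:
    """Gene metadata CSV -> GeneRecords; duplicate symbols are an error."""
    df = pd.read_csv(path)
    _require_columns(df, GENE_META_COLUMNS, "gene metadata")
    dup = df["symbol"][df["symbol"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene symbol(s): {sorted(set(dup))}")
    records = []
    for row in df.itertuples():
        go = () if pd.isna(row.go_category) or row.go_category == "" else (
            tuple(str(row.go_category).split(";"))
        )
        subgroup = None if pd.isna(row.subgroup) else str(row.subgroup)
        records.append(
            GeneRecord(
                symbol=str(row.symbol),
                accession="" if pd.isna(row.accession) else str(row.accession),
                are_status=None if pd.isna(row.are_status) else str(row.are_status),
                are_class=str(row.are_class),
                are_score=float(row.are_score),
                in_ared=bool(row.in_ared),
                go_category=go,
                subgroup=subgroup,
                log2fc=float(row.log2fc),
                adj_p=float(row.adj_p),
                efficiency=float(row.efficiency),
                is_reference=bool(row.is_reference),
            )
        )
    return records


def write_gene_metadata(records: Iterable[GeneRecord], path: PathLike) -> None:
    rows = []
    for rec in records:
        row = dataclasses.asdict(rec)
        row["go_category"] = ";".join(rec.go_category)
        rows.append(row)
    pd.DataFrame(rows)[GENE_META_COLUMNS].to_csv(path, index=False)
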