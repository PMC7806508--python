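"""Readers and writers for the pipeline's on-disk formats.

Counts travel as TSV (genes as rows, first column gene id) or as a
MatrixMarket triple (matrix + row-name and column-name files); sample
sheets and tables as TSV; gene sets as GMT; cancer-testis lists as plain
text, one symbol per line; IHC cohorts as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import io as spio
from scipy import sparse


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate gene ids in count matrix")
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label=counts.index.name or "gene_id")


def read_counts_mtx(matrix_path, gene_path, sample_path) -> pd.DataFrame:
    mat = spio.mmread(matrix_path)
    genes = Path(gene_path).read_text().split()
    samples = Path(sample_path).read_text().split()
    arr = mat.toarray() if sparse.issparse(mat) else mat
    return pd.DataFrame(arr, index=genes, columns=samples)


def write_counts_mtx(counts: pd.DataFrame, matrix_path, gene_path, sample_path) -> None:
    spio.mmwrite(str(matrix_path), sparse.csr_matrix(counts.to_numpy()))
    Path(gene_path).write_text("\n".join(map(str, counts.index)) + "\n")
    Path(sample_path).write_text("\n".join(map(str, counts.columns)) + "\n")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "class"} - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    collection: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *members = fields
        collection[name] = [m for m in members if m]
    return collection


def write_gmt(collection: Mapping[str, Sequence[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    lines = [
        "\t".join([name, descriptions.get(name, "na"), *members])
        for name, members in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(genes: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_ihc_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need_counts = {"tumor_class", "marker", "n_total", "n_positive"}
    need_records = {"tumor_class", "marker", "pct_intensity_0"}
    if not (need_counts <= set(df.columns) or need_records <= set(df.columns)):
        raise ValueError(
            "IHC input needs either per-sample intensity percentages or cohort counts"
        )
    return df


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
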