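"""Readers and writers for the plain-text interchange formats.

Counts: TSV (genes in rows, header row of sample IDs) or MatrixMarket
``.mtx`` with sidecar row/column index files. Clinical tables: CSV with a
strict column schema. Gene sets: GMT (tab-separated name, description,
genes...).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import GeneCountMatrix, validate_clinical

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_clinical_csv",
    "write_clinical_csv",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
]


def read_counts_tsv(path) -> GeneCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeneCountMatrix(df)


def write_counts_tsv(counts: GeneCountMatrix, path) -> None:
    counts.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_mtx(mtx_path, genes_path=None, samples_path=None) -> GeneCountMatrix:
    """Read counts from MatrixMarket plus row (gene) / column (sample) index files."""
    mtx_path = Path(mtx_path)
    genes_path = genes_path or mtx_path.with_suffix(".genes.txt")
    samples_path = samples_path or mtx_path.with_suffix(".samples.txt")
    mat = scipy.io.mmread(mtx_path)
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    df = pd.DataFrame(
        np.asarray(scipy.sparse.coo_matrix(mat).todense()), index=genes, columns=samples
    )
    return GeneCountMatrix(df)


def write_counts_mtx(counts: GeneCountMatrix, mtx_path) -> None:
    mtx_path = Path(mtx_path)
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(counts.counts.to_numpy()))
    mtx_path.with_suffix(".genes.txt").write_text("\n".join(counts.gene_ids) + "\n")
    mtx_path.with_suffix(".samples.txt").write_text("\n".join(counts.sample_ids) + "\n")


def read_clinical_csv(path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if "response_binary" in df:
        df["response_binary"] = df["response_binary"].astype(bool)
    if validate:
        validate_clinical(df)
    return df


def write_clinical_csv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index_label="sample_id")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set library: one set per line, name TAB description TAB genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:60]!r}")
        name, genes = parts[0], [g for g in parts[2:] if g]
        if name in sets:
            raise ValueError(f"duplicate gene-set name: {name}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    lines = [
        "\t".join([name, description or name] + list(genes)) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path) -> list[str]:
    """Plain one-gene-per-line list (e.g. a panel content file)."""
    return [g.strip() for g in Path(path).read_text().splitlines() if g.strip()]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
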