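"""Readers and writers for the on-disk exchange formats.

10x-style bundles (matrix.mtx + features.tsv + barcodes.tsv + cell_meta.tsv),
GMT gene-set files, and YAML generator-parameter files.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .simulate import CountMatrix, GenParams


def write_tenx(matrix: CountMatrix, path: str | os.PathLike) -> None:
    """Write a CountMatrix as an uncompressed 10x-style directory.

    matrix.mtx holds genes x cells counts (Matrix Market, 1-based
    coordinates); features.tsv is (gene_id, gene_symbol, feature_type);
    barcodes.tsv is one barcode per line; cell_meta.tsv carries the per-cell
    metadata keyed by barcode. Round-trips bit-exactly through
    :func:`read_tenx`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(path / "matrix.mtx"), sp.coo_matrix(matrix.counts), field="integer"
    )
    feats = pd.DataFrame(
        {
            "gene_id": matrix.gene_meta["gene_id"],
            "gene_symbol": matrix.gene_meta["gene_id"],
            "feature_type": "Gene Expression",
        }
    )
    feats.to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    matrix.cell_meta["cell_id"].to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    matrix.cell_meta.to_csv(path / "cell_meta.tsv", sep="\t", index=False)
    gm = matrix.gene_meta.copy()
    gm.to_csv(path / "gene_meta.tsv", sep="\t", index=False)


def read_tenx(path: str | os.PathLike) -> CountMatrix:
    """Read a 10x-style directory written by :func:`write_tenx`.

    Plain Cell-Ranger output (no cell_meta.tsv / gene_meta.tsv) is accepted:
    metadata then holds only barcodes and gene ids, with mitochondrial genes
    flagged by the conventional ``mt-`` symbol prefix.
    """
    path = Path(path)
    counts = sp.csr_matrix(scipy.io.mmread(str(path / "matrix.mtx"))).astype(np.int32)
    feats = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    try:
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    except pd.errors.EmptyDataError:
        barcodes = pd.Series([], dtype=str)

    gm_path = path / "gene_meta.tsv"
    if gm_path.exists():
        gene_meta = pd.read_csv(gm_path, sep="\t")
        gene_meta["panels"] = gene_meta["panels"].fillna("")
    else:
        ids = feats[0].astype(str)
        gene_meta = pd.DataFrame(
            {
                "gene_id": ids,
                "is_mito": ids.str.lower().str.startswith("mt-"),
                "panels": "",
            }
        )
    cm_path = path / "cell_meta.tsv"
    if cm_path.exists():
        cell_meta = pd.read_csv(cm_path, sep="\t")
        cell_meta["cell_id"] = cell_meta["cell_id"].astype(str)
    else:
        cell_meta = pd.DataFrame({"cell_id": barcodes})
    if counts.shape[1] == 0:
        # mmread of an empty matrix keeps the declared shape; align metadata.
        cell_meta = cell_meta.iloc[0:0]
    return CountMatrix(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_params(params: GenParams, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=False)


def read_params(path: str | os.PathLike) -> GenParams:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return GenParams(**data)
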