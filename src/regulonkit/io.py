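"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel either as a 10x-style MTX triplet directory
(``matrix.mtx`` features x barcodes, ``barcodes.tsv``, ``features.tsv``,
optional ``metadata.tsv``) or as a dense TSV with cells in rows and genes in
columns.  In memory a count matrix is an :class:`anndata.AnnData` with integer
counts in CSC sparse form, cell metadata in ``.obs`` and gene symbols as
``.var_names``.  Every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_tsv_matrix",
    "write_tsv_matrix",
    "write_json",
    "read_json",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def _check_duplicates(ids, what: str) -> None:
    dupes = sorted(g for g, c in Counter(ids).items() if c > 1)
    if dupes:
        raise FormatError(f"duplicate {what} identifiers: {dupes}")


def read_count_matrix(path: str | Path, format: str = "mtx10x") -> ad.AnnData:
    """Read a cells x genes integer count matrix.

    ``mtx10x`` expects a directory containing ``matrix.mtx`` (features x
    barcodes), ``barcodes.tsv`` and ``features.tsv``; ``tsv`` expects a single
    table with cell ids in the first column and gene symbols in the header.
    Sparse and dense inputs with the same logical content produce identical
    AnnData objects.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx10x":
        mtx = path / "matrix.mtx"
        barcodes_f = path / "barcodes.tsv"
        features_f = path / "features.tsv"
        for f in (mtx, barcodes_f, features_f):
            if not f.exists():
                raise FileNotFoundError(f"10x bundle incomplete: missing {f.name} in {path}")
        first = mtx.open().readline()
        if not first.startswith("%%MatrixMarket"):
            raise FormatError(f"{mtx}: malformed header line 1: {first.strip()!r}")
        m = sp.csc_matrix(scipy.io.mmread(mtx))  # features x barcodes
        barcodes = [l.split("\t")[0] for l in barcodes_f.read_text().splitlines() if l]
        features = [l.split("\t")[0] for l in features_f.read_text().splitlines() if l]
        _check_duplicates(features, "gene")
        _check_duplicates(barcodes, "cell")
        if m.shape != (len(features), len(barcodes)):
            raise FormatError(
                f"{mtx}: shape {m.shape} inconsistent with {len(features)} features "
                f"x {len(barcodes)} barcodes"
            )
        adata = ad.AnnData(
            X=sp.csc_matrix(m.T).astype(np.int64),
            obs=pd.DataFrame(index=pd.Index(barcodes, name="cell")),
            var=pd.DataFrame(index=pd.Index(features, name="gene")),
        )
        meta_f = path / "metadata.tsv"
        if meta_f.exists():
            meta = pd.read_csv(meta_f, sep="\t", index_col=0)
            adata.obs = meta.reindex(adata.obs_names)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        _check_duplicates(list(df.columns), "gene")
        _check_duplicates(list(df.index), "cell")
        if not np.issubdtype(df.to_numpy().dtype, np.number):
            raise FormatError(f"{path}: non-numeric entries in count matrix")
        adata = ad.AnnData(
            X=sp.csc_matrix(df.to_numpy().astype(np.int64)),
            obs=pd.DataFrame(index=pd.Index(df.index.astype(str), name="cell")),
            var=pd.DataFrame(index=pd.Index(df.columns.astype(str), name="gene")),
        )
    else:
        raise ValueError(f"unknown format {format!r}; expected 'mtx10x' or 'tsv'")
    return adata


def write_count_matrix(adata: ad.AnnData, path: str | Path, format: str = "mtx10x") -> None:
    """Write a count matrix in the format ``read_count_matrix`` reads back."""
    path = Path(path)
    if format == "mtx10x":
        path.mkdir(parents=True, exist_ok=True)
        X = sp.coo_matrix(adata.X).T  # features x barcodes
        scipy.io.mmwrite(path / "matrix.mtx", X, field="integer")
        (path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in adata.obs_names))
        (path / "features.tsv").write_text("".join(f"{g}\n" for g in adata.var_names))
        if adata.obs.shape[1]:
            adata.obs.rename_axis("cell").to_csv(path / "metadata.tsv", sep="\t")
    elif format == "tsv":
        X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
        pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names).rename_axis(
            "cell"
        ).to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_gene_list(path: str | Path) -> list[str]:
    """Read one gene symbol per line, preserving order, dropping duplicates."""
    lines = [l.strip() for l in Path(path).read_text().splitlines()]
    symbols = [l for l in lines if l]
    if not symbols:
        raise FormatError(f"{path}: empty gene list")
    seen: dict[str, None] = {}
    n_dupes = 0
    for s in symbols:
        if s in seen:
            n_dupes += 1
        seen[s] = None
    if n_dupes:
        logger.warning("%s: removed %d duplicate symbols", path, n_dupes)
    return list(seen)


def write_gene_list(symbols, path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in symbols))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: term, description, genes, tab-separated."""
    sets: dict[str, set[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {i} has fewer than 3 tab-separated fields")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with Path(path).open("w") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, description, *sorted(genes)]) + "\n")


def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
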