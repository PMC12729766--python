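"""Reading and writing expression matrices.

Two on-disk dialects are supported:

* 10x-style Matrix Market directory: ``matrix.mtx`` (genes x cells, transposed
  to cells x genes on read) plus ``features.tsv``/``genes.tsv`` and
  ``barcodes.tsv``, each optionally gzipped.
* Dense CSV/TSV: header row = gene ids, first column = cell ids.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError
from .matrix import SCALE_COUNTS, ExpressionMatrix

PathLike = Union[str, Path]


def _find_companion(d: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = d / name
            if p.exists():
                return p
    raise FormatError(f"none of {stems} found in {d}")


def _read_tsv_column(path: Path, column: int = 0) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    return [row[min(column, len(row) - 1)] for row in rows]


def read_matrix(path: PathLike, format: Optional[str] = None,
                scale_tag: str = SCALE_COUNTS) -> ExpressionMatrix:
    """Load an expression matrix, normalizing orientation to cells x genes.

    ``format`` is ``"mtx_dir"`` or ``"csv"``; inferred from the path when None
    (a directory implies mtx_dir). Pass ``scale_tag="cp10k_log1p"`` when the
    file holds normalized (possibly non-count) values.
    """
    path = Path(path)
    if format is None:
        format = "mtx_dir" if path.is_dir() else "csv"
    if format == "mtx_dir":
        return _read_mtx_dir(path, scale_tag)
    if format == "csv":
        return _read_csv(path, scale_tag)
    raise FormatError(f"unknown format {format!r}")


def _read_mtx_dir(d: Path, scale_tag: str = SCALE_COUNTS) -> ExpressionMatrix:
    if not d.is_dir():
        raise FormatError(f"{d} is not a directory")
    mtx = _find_companion(d, ("matrix.mtx",))
    feat = _find_companion(d, ("features.tsv", "genes.tsv"))
    barc = _find_companion(d, ("barcodes.tsv",))

    if mtx.suffix == ".gz":
        with gzip.open(mtx, "rb") as fh:
            M = scipy.io.mmread(fh)
    else:
        M = scipy.io.mmread(mtx)
    M = np.asarray(scipy.sparse.coo_matrix(M).todense(), dtype=np.float64)

    gene_ids = _read_tsv_column(feat, column=0)
    cell_ids = _read_tsv_column(barc, column=0)

    # 10x writes genes x cells; transpose so cells are rows in memory.
    if M.shape == (len(gene_ids), len(cell_ids)):
        M = M.T
    elif M.shape != (len(cell_ids), len(gene_ids)):
        raise FormatError(
            f"matrix.mtx is {M.shape} but {feat.name} lists {len(gene_ids)} "
            f"genes and {barc.name} lists {len(cell_ids)} barcodes"
        )
    return ExpressionMatrix(values=M, gene_ids=gene_ids, cell_ids=cell_ids,
                            scale_tag=scale_tag)


def _read_csv(path: Path, scale_tag: str = SCALE_COUNTS) -> ExpressionMatrix:
    if not path.exists():
        raise FormatError(f"{path} does not exist")
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=np.float64),
        gene_ids=[str(c) for c in df.columns],
        cell_ids=[str(i) for i in df.index],
        scale_tag=scale_tag,
    )


def write_matrix(m: ExpressionMatrix, path: PathLike,
                 format: str = "mtx_dir") -> None:
    """Write a matrix as an MTX directory or a dense CSV."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        # genes x cells on disk, matching the 10x convention.
        sparse = scipy.sparse.coo_matrix(m.values.T)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sparse)
        with open(path / "genes.tsv", "w") as fh:
            for g in m.gene_ids:
                fh.write(f"{g}\t{g}\n")
        with open(path / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(m.cell_ids) + "\n")
    elif format == "csv":
        df = pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids)
        df.to_csv(path)
    else:
        raise FormatError(f"unknown format {format!r}")


def read_gene_lengths(path: PathLike) -> dict[str, float]:
    """Read a two-column TSV of gene id -> transcript length in bases."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length"])
    return dict(zip(df["gene_id"].astype(str), df["length"].astype(float)))


def read_cell_labels(path: PathLike) -> dict[str, str]:
    """Read a two-column TSV of cell id -> cell-type label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"])
    return dict(zip(df["cell_id"].astype(str), df["label"].astype(str)))
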