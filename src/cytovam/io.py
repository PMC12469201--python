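"""Readers and writers for the formats the tool touches.

Supported inputs:

* 10x-style MTX directories (``matrix.mtx[.gz]`` + features/genes +
  barcodes files).  On disk the matrix is genes x cells (the 10x
  convention); it is transposed to the internal cells x genes orientation
  on read.
* Dense delimited text (comma or tab), header row of gene ids, first
  column of cell ids.
* wGMT, a signed weighted gene-set dialect of GMT: a ``#wgmt1`` header
  line, then one set per line with TAB-separated fields
  ``name  sign  gene=weight  gene=weight ...`` where sign is ``positive``
  or ``negative``.
* A two-column TSV of per-cell condition labels.
"""

from __future__ import annotations

import gzip
import os
import warnings
from typing import IO, Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    ExpressionMatrix,
    LabeledDataset,
    Sign,
    SignatureCollection,
    SignedSignature,
    WeightedGeneSet,
)

__all__ = [
    "read_expression",
    "write_expression",
    "log_normalize",
    "read_weighted_sets",
    "write_weighted_sets",
    "read_labels",
    "write_labels",
    "read_gmt",
    "read_lr_map",
]

WGMT_HEADER = "#wgmt1"


def _open_maybe_gz(path: str, mode: str = "rt") -> IO:
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_first(directory: str, names: Iterable[str]) -> str | None:
    for name in names:
        p = os.path.join(directory, name)
        if os.path.exists(p):
            return p
    return None


def _read_id_file(path: str, what: str) -> list[str]:
    """Read a features/barcodes TSV, auto-detecting the id column.

    For multi-column feature files the second column (gene symbol in the
    10x layout) is preferred when its entries are unique and non-empty;
    otherwise column 1 is used.
    """
    with _open_maybe_gz(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise ValueError(f"{what} file {path!r} is empty")
    col = 0
    if all(len(r) >= 2 for r in rows):
        second = [r[1] for r in rows]
        if all(second) and len(set(second)) == len(second):
            col = 1
    return [r[col] for r in rows]


def read_expression(path: str, format: str = "auto") -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    path : str
        For ``mtx_dir``, a directory holding ``matrix.mtx[.gz]``,
        ``features.tsv[.gz]`` (or ``genes.tsv``) and ``barcodes.tsv[.gz]``.
        For ``dense_delim``, a delimited text file with gene ids in the
        header row and cell ids in the first column.
    format : {"auto", "mtx_dir", "dense_delim"}
        ``auto`` picks ``mtx_dir`` when ``path`` is a directory.

    Returns
    -------
    ExpressionMatrix
        Cells x genes, regardless of the on-disk orientation.
    """
    if format == "auto":
        format = "mtx_dir" if os.path.isdir(path) else "dense_delim"
    if format == "mtx_dir":
        return _read_mtx_dir(path)
    if format == "dense_delim":
        return _read_dense(path)
    raise ValueError(f"unknown format {format!r}")


def _read_mtx_dir(directory: str) -> ExpressionMatrix:
    mtx = _find_first(directory, ["matrix.mtx", "matrix.mtx.gz"])
    feats = _find_first(
        directory,
        ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"],
    )
    bcs = _find_first(directory, ["barcodes.tsv", "barcodes.tsv.gz"])
    if mtx is None or feats is None or bcs is None:
        raise FileNotFoundError(
            f"{directory!r} must contain matrix.mtx(.gz), features/genes and barcodes files"
        )
    if os.path.getsize(mtx) == 0:
        raise ValueError(f"matrix file {mtx!r} is empty")
    with _open_maybe_gz(mtx, "rb") as fh:
        mat = scipy.io.mmread(fh)
    mat = scipy.sparse.coo_matrix(mat)
    genes = _read_id_file(feats, "features")
    cells = _read_id_file(bcs, "barcodes")
    # 10x convention: rows are genes, columns are cells.
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix is {mat.shape[0]} x {mat.shape[1]} but there are "
            f"{len(genes)} features and {len(cells)} barcodes"
        )
    dense = np.asarray(mat.todense(), dtype=np.float64).T
    return ExpressionMatrix(dense, genes, cells)


def _read_dense(path: str) -> ExpressionMatrix:
    if os.path.getsize(path) == 0:
        raise ValueError(f"matrix file {path!r} is empty")
    with _open_maybe_gz(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"matrix file {path!r} has no gene columns")
    return ExpressionMatrix(
        df.to_numpy(dtype=np.float64),
        [str(c) for c in df.columns],
        [str(i) for i in df.index],
    )


def write_expression(expr: ExpressionMatrix, path: str, format: str = "dense_delim") -> None:
    """Write an ExpressionMatrix as a dense CSV or an MTX directory."""
    if format == "dense_delim":
        expr.to_dataframe().to_csv(path)
    elif format == "mtx_dir":
        os.makedirs(path, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(expr.values.T)  # genes x cells on disk
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sparse)
        with open(os.path.join(path, "features.tsv"), "w") as fh:
            fh.write("\n".join(expr.gene_ids) + "\n")
        with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(expr.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def log_normalize(
    counts,
    gene_ids: list[str] | None = None,
    cell_ids: list[str] | None = None,
    scale_factor: float = 1e4,
) -> ExpressionMatrix:
    """Library-size normalize and natural-log transform raw counts.

    value[c, g] = ln(1 + counts[c, g] * scale_factor / total_counts[c])

    Cells with zero total counts are dropped with a warning.  Accepts a
    raw-count ``ExpressionMatrix`` or a bare array plus id lists.
    """
    if isinstance(counts, ExpressionMatrix):
        gene_ids = counts.gene_ids
        cell_ids = counts.cell_ids
        counts = counts.values
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D matrix")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ValueError("counts must be finite and non-negative")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    n_cells, n_genes = counts.shape
    if gene_ids is None:
        gene_ids = [f"G{i + 1}" for i in range(n_genes)]
    if cell_ids is None:
        cell_ids = [f"C{i + 1}" for i in range(n_cells)]
    totals = counts.sum(axis=1)
    keep = totals > 0
    if not np.all(keep):
        dropped = [cell_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropping {len(dropped)} cell(s) with zero total counts: {dropped[:10]}",
            UserWarning,
            stacklevel=2,
        )
        counts = counts[keep]
        cell_ids = [c for c, k in zip(cell_ids, keep) if k]
        totals = totals[keep]
    values = np.log1p(counts * (scale_factor / totals[:, None]))
    return ExpressionMatrix(values, list(gene_ids), list(cell_ids))


# ---------------------------------------------------------------------------
# wGMT


def write_weighted_sets(collection: SignatureCollection, path: str) -> None:
    """Serialize a SignatureCollection in the wGMT dialect.

    Weights are printed with full precision (%.17g) so the round trip is
    lossless; empty signed sets are written as lines with no gene tokens so
    the cytokine survives the round trip.
    """
    with open(path, "w") as fh:
        fh.write(WGMT_HEADER + "\n")
        fh.write(f"#num_genes\t{collection.num_genes_requested}\n")
        for name, sig in collection.cytokines.items():
            for gs in (sig.positive, sig.negative):
                tokens = [f"{g}={w:.17g}" for g, w in zip(gs.genes, gs.weights)]
                fh.write("\t".join([name, gs.sign.value, *tokens]) + "\n")


def read_weighted_sets(path: str) -> SignatureCollection:
    """Parse a wGMT file into a SignatureCollection.

    Provenance log2fc is reconstructed as sign x weight; p-values are NaN
    (the file format does not carry them).
    """
    sets: dict[str, dict[Sign, WeightedGeneSet]] = {}
    num_genes = 60
    with _open_maybe_gz(path) as fh:
        first = fh.readline().strip()
        if first != WGMT_HEADER:
            raise ValueError(f"{path!r}: missing {WGMT_HEADER} header line")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                fields = line.split("\t")
                if fields[0] == "#num_genes" and len(fields) == 2:
                    num_genes = int(fields[1])
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path!r} line {lineno}: expected name, sign, tokens")
            name, sign_str = fields[0], fields[1]
            try:
                sign = Sign(sign_str)
            except ValueError:
                raise ValueError(
                    f"{path!r} line {lineno}: sign must be 'positive' or 'negative', got {sign_str!r}"
                ) from None
            genes: list[str] = []
            weights: list[float] = []
            for tok in fields[2:]:
                if "=" not in tok:
                    raise ValueError(f"{path!r} line {lineno}: malformed token {tok!r}")
                gene, _, wstr = tok.partition("=")
                try:
                    w = float(wstr)
                except ValueError:
                    raise ValueError(
                        f"{path!r} line {lineno}: non-numeric weight {wstr!r} for gene {gene!r}"
                    ) from None
                genes.append(gene)
                weights.append(w)
            per = sets.setdefault(name, {})
            if sign in per:
                raise ValueError(f"{path!r} line {lineno}: duplicate {sign.value} set for {name}")
            try:
                per[sign] = WeightedGeneSet(name, sign, genes, np.asarray(weights))
            except ValueError as exc:
                raise ValueError(f"{path!r} line {lineno}: {exc}") from None

    cytokines: dict[str, SignedSignature] = {}
    prov_rows = []
    for name, per in sets.items():
        pos = per.get(Sign.positive, WeightedGeneSet(name, Sign.positive, [], []))
        neg = per.get(Sign.negative, WeightedGeneSet(name, Sign.negative, [], []))
        shared = set(pos.genes) & set(neg.genes)
        if shared:
            raise ValueError(
                f"{path!r}: gene(s) {sorted(shared)} appear in both signs of {name}"
            )
        cytokines[name] = SignedSignature(pos, neg)
        for gs, s in ((pos, 1.0), (neg, -1.0)):
            for g, w in zip(gs.genes, gs.weights):
                prov_rows.append((name, g, s * w, np.nan, np.nan))
    provenance = pd.DataFrame(
        prov_rows, columns=["cytokine", "gene", "log2fc", "p_value", "p_adjusted"]
    )
    return SignatureCollection(cytokines, provenance, num_genes_requested=num_genes)


# ---------------------------------------------------------------------------
# Small helper formats


def read_labels(path: str) -> pd.Series:
    """Read a two-column TSV (cell_id, label) into a Series keyed by cell."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path!r}: expected two TAB-separated columns (cell_id, label)")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="label")


def write_labels(labels: pd.Series | dict, path: str) -> None:
    pd.Series(labels).to_csv(path, sep="\t", header=False)


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read a standard (unweighted) GMT file: name, description, genes."""
    out: dict[str, list[str]] = {}
    with _open_maybe_gz(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path!r} line {lineno}: expected name, description, genes")
            out[fields[0]] = [g for g in fields[2:] if g]
    return out


def read_lr_map(path: str) -> dict[str, list[str]]:
    """Read a ligand->receptors TSV: ligand TAB comma-separated receptors."""
    out: dict[str, list[str]] = {}
    with _open_maybe_gz(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[1].strip():
                raise ValueError(
                    f"{path!r} line {lineno}: expected 'ligand<TAB>rec1,rec2,...'"
                )
            out[fields[0]] = [r.strip() for r in fields[1].split(",") if r.strip()]
    return out


def make_labeled_dataset(expr: ExpressionMatrix, labels: pd.Series) -> LabeledDataset:
    """Align a label Series to an ExpressionMatrix's cells."""
    missing = [c for c in expr.cell_ids if c not in labels.index]
    if missing:
        raise ValueError(f"labels missing for cells: {missing[:10]}")
    return LabeledDataset(expr, [labels[c] for c in expr.cell_ids])
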