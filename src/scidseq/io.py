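"""Readers and writers for count matrices and reports.

Two on-disk dialects, both lossless for values, well/antibody metadata and
the processing-state tag:

* TSV — one table per matrix: a ``# scidseq CountMatrix state=...`` header
  line, well metadata columns first, then one column per antibody. Antibody
  metadata travels in a ``<stem>.antibodies.tsv`` sidecar.
* MTX — a directory with ``matrix.mtx`` (MatrixMarket), ``rows.tsv``,
  ``cols.tsv`` and ``meta.json``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .demux import CountMatrix

_META_COLS = ["well_type", "gate_label", "total_umis"]
_HEADER_PREFIX = "# scidseq CountMatrix state="


class FormatError(ValueError):
    pass


def _sidecar_path(path: Path) -> Path:
    return path.parent / (path.stem + ".antibodies.tsv")


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write a matrix as TSV (or MTX when ``path`` is an existing directory
    or has no suffix)."""
    path = Path(path)
    if path.is_dir() or path.suffix == "":
        write_count_matrix_mtx(matrix, path)
        return
    meta = matrix.row_meta.copy()
    for col in _META_COLS:
        if col not in meta.columns:
            meta[col] = "" if col != "total_umis" else 0
    table = pd.concat([meta[_META_COLS], matrix.values], axis=1)
    with open(path, "w") as fh:
        fh.write(f"{_HEADER_PREFIX}{matrix.state}\n")
        table.to_csv(fh, sep="\t", index=True, index_label="well_id")
    matrix.col_meta.to_csv(_sidecar_path(path), sep="\t", index=True)


def read_count_matrix(path: str | Path) -> CountMatrix:
    path = Path(path)
    if path.is_dir():
        return read_count_matrix_mtx(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if not first.startswith(_HEADER_PREFIX):
        raise FormatError(f"{path}: missing state header line")
    state = first[len(_HEADER_PREFIX):]
    table = pd.read_csv(path, sep="\t", skiprows=1, index_col="well_id",
                        float_precision="round_trip")
    missing = [c for c in _META_COLS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {missing}")
    row_meta = table[_META_COLS].copy()
    row_meta["gate_label"] = row_meta["gate_label"].fillna("none")
    values = table.drop(columns=_META_COLS)
    if state in ("raw", "filtered", "subsampled"):
        values = values.astype(np.int64)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        col_meta = pd.read_csv(sidecar, sep="\t", index_col=0, dtype=str,
                               keep_default_na=False)
        if not col_meta.index.equals(values.columns):
            raise FormatError(
                f"{sidecar}: antibody metadata does not match matrix columns"
            )
    else:
        warnings.warn(f"no antibody metadata sidecar at {sidecar}")
        col_meta = pd.DataFrame(index=values.columns.rename("antibody_name"))
    return CountMatrix(values=values, row_meta=row_meta, col_meta=col_meta, state=state)


def write_count_matrix_mtx(matrix: CountMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(matrix.values.to_numpy())
    scipy.io.mmwrite(outdir / "matrix.mtx", sparse, precision=17)
    matrix.row_meta.to_csv(outdir / "rows.tsv", sep="\t", index=True)
    matrix.col_meta.to_csv(outdir / "cols.tsv", sep="\t", index=True)
    (outdir / "meta.json").write_text(json.dumps({"state": matrix.state}) + "\n")


def read_count_matrix_mtx(indir: str | Path) -> CountMatrix:
    indir = Path(indir)
    for name in ("matrix.mtx", "rows.tsv", "cols.tsv", "meta.json"):
        if not (indir / name).exists():
            raise FormatError(f"{indir}: missing {name}")
    state = json.loads((indir / "meta.json").read_text())["state"]
    arr = scipy.io.mmread(indir / "matrix.mtx").toarray()
    row_meta = pd.read_csv(indir / "rows.tsv", sep="\t", index_col=0,
                           float_precision="round_trip")
    row_meta["gate_label"] = row_meta["gate_label"].fillna("none")
    col_meta = pd.read_csv(indir / "cols.tsv", sep="\t", index_col=0, dtype=str,
                           keep_default_na=False)
    if arr.shape != (len(row_meta), len(col_meta)):
        raise FormatError(
            f"{indir}: matrix shape {arr.shape} does not match metadata "
            f"({len(row_meta)} rows, {len(col_meta)} cols)"
        )
    dtype = np.int64 if state in ("raw", "filtered", "subsampled") else float
    values = pd.DataFrame(
        arr.astype(dtype), index=row_meta.index,
        columns=pd.Index(col_meta.index.to_list()),
    )
    return CountMatrix(values=values, row_meta=row_meta, col_meta=col_meta, state=state)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
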