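"""Quality control and normalization of well-level UMI count matrices.

Empty wells on the sorted plate received no cell, so their UMI totals measure
technical background (free conjugate carry-over, cross-well contamination).
Cell wells are filtered on total counts, equalized for sequencing depth by
rarefaction (subsampling without replacement), and each antibody is min-max
scaled to [0, 1] across cells so abundant epitopes do not dominate downstream
analyses. For phospho epitopes with a measured total-protein partner, the
per-cell phospho/total ratio corrects activity for abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demux import CountMatrix
from .panel import Panel, PlateLayout


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    """Background estimate and filtering summary for one plate.

    ``background_fraction`` = median empty-well total / median cell-well
    total; ``fold_separation`` is its reciprocal. Medians are used for
    robustness to outlier wells.
    """

    empty_well_totals: dict[str, int] = field(default_factory=dict)
    cell_well_totals: dict[str, int] = field(default_factory=dict)
    background_fraction: float | None = None
    fold_separation: float | None = None
    cells_retained: int | None = None
    cells_dropped: int | None = None
    filter_threshold_used: int | None = None

    def to_dict(self) -> dict:
        return {
            "background_fraction": self.background_fraction,
            "fold_separation": self.fold_separation,
            "cells_retained": self.cells_retained,
            "cells_dropped": self.cells_dropped,
            "filter_threshold_used": self.filter_threshold_used,
            "n_empty_wells": len(self.empty_well_totals),
            "n_cell_wells": len(self.cell_well_totals),
            "empty_well_totals": dict(self.empty_well_totals),
            "cell_well_totals": dict(self.cell_well_totals),
        }


@dataclass
class RatioMatrix:
    """Per-cell phospho/total ratios, one column per paired phospho epitope."""

    values: pd.DataFrame
    pseudocount: float

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ValueError("ratios must be finite and non-negative")


def estimate_background(matrix: CountMatrix, plate: PlateLayout | None = None) -> QCReport:
    """Estimate technical background from empty-well UMI totals.

    Requires a raw matrix that still carries its empty-well rows. When no
    empty wells are present, the background fields are left unset with a
    warning rather than failing.
    """
    totals = matrix.values.sum(axis=1)
    well_type = matrix.row_meta["well_type"]
    empty = totals[well_type == "empty"]
    cells = totals[well_type == "cell"]
    if cells.empty:
        raise QCError("no cell wells in matrix")
    report = QCReport(
        empty_well_totals={w: int(v) for w, v in empty.items()},
        cell_well_totals={w: int(v) for w, v in cells.items()},
    )
    if empty.empty:
        warnings.warn("no empty wells present; background unavailable")
        return report
    med_empty = float(np.median(empty.to_numpy()))
    med_cell = float(np.median(cells.to_numpy()))
    if med_cell > 0:
        report.background_fraction = med_empty / med_cell
    if med_empty > 0:
        report.fold_separation = med_cell / med_empty
    elif med_cell > 0:
        report.background_fraction = 0.0
        report.fold_separation = float("inf")
    return report


def default_filter_threshold(matrix: CountMatrix, floor: int = 500) -> int:
    """Default QC policy: keep cells with total >= 10x the median empty-well
    total, with a floor. The large cell/empty separation motivates the 10x
    guard band."""
    well_type = matrix.row_meta["well_type"]
    empty = matrix.values.sum(axis=1)[well_type == "empty"]
    if empty.empty:
        return floor
    return max(floor, int(10 * np.median(empty.to_numpy())))


def filter_cells(
    matrix: CountMatrix,
    min_total: int | str = "auto",
    report: QCReport | None = None,
) -> CountMatrix:
    """Drop empty wells and low-count cell wells.

    ``min_total`` is an explicit integer threshold or ``"auto"`` (10x median
    empty-well total, floor 500). Raises when no cell survives.
    """
    if matrix.state != "raw":
        raise QCError(f"filter_cells expects a raw matrix, got {matrix.state!r}")
    threshold = (
        default_filter_threshold(matrix) if min_total == "auto" else int(min_total)
    )
    cells = matrix.cells()
    totals = cells.values.sum(axis=1)
    keep = totals[totals >= threshold].index
    if keep.empty:
        raise QCError(
            f"no cell wells have total UMIs >= {threshold}; "
            f"max observed is {int(totals.max())}"
        )
    if report is not None:
        report.filter_threshold_used = threshold
        report.cells_retained = len(keep)
        report.cells_dropped = int(len(totals) - len(keep))
    out = matrix.with_values(matrix.values.loc[keep], "filtered")
    out.row_meta["total_umis"] = out.values.sum(axis=1)
    return out


def subsample_counts(
    matrix: CountMatrix, depth: int | str = "min", seed: int = 0
) -> CountMatrix:
    """Rarefy each cell to the same depth without replacement.

    Each row is drawn from its own UMI multiset as a multivariate
    hypergeometric sample, so every row's total equals ``depth`` exactly and
    no entry exceeds its original count. ``depth="min"`` uses the minimum
    retained cell total (discards no cells); with an explicit depth, cells
    below it are dropped with a warning.
    """
    if matrix.state != "filtered":
        raise QCError(f"subsample_counts expects a filtered matrix, got {matrix.state!r}")
    totals = matrix.values.sum(axis=1)
    if depth == "min":
        depth_i = int(totals.min())
    else:
        depth_i = int(depth)
    if depth_i <= 0:
        raise QCError(f"subsampling depth must be positive, got {depth_i}")
    keep = totals[totals >= depth_i].index
    if len(keep) < len(totals):
        warnings.warn(
            f"{len(totals) - len(keep)} cells below depth {depth_i} dropped"
        )
    if keep.empty:
        raise QCError(f"no cells have total >= depth {depth_i}")
    rng = np.random.default_rng(seed)
    values = matrix.values.loc[keep]
    out = np.empty(values.shape, dtype=np.int64)
    arr = values.to_numpy()
    for i in range(arr.shape[0]):
        out[i] = rng.multivariate_hypergeometric(arr[i], depth_i)
    df = pd.DataFrame(out, index=values.index, columns=values.columns)
    result = matrix.with_values(df, "subsampled")
    result.row_meta["total_umis"] = df.sum(axis=1)
    return result


def scale_minmax(matrix: CountMatrix) -> CountMatrix:
    """Scale each antibody column to [0, 1] across cells: (x - min)/(max - min).

    Zero-variance columns are set to all zeros with a warning.
    """
    if matrix.shape[0] < 2:
        raise QCError("scaling needs at least 2 cells")
    arr = matrix.values.to_numpy(dtype=float)
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    span = hi - lo
    degenerate = span == 0
    if degenerate.any():
        names = list(matrix.values.columns[degenerate])
        warnings.warn(f"zero-variance columns set to 0: {names}")
    span_safe = np.where(degenerate, 1.0, span)
    scaled = (arr - lo) / span_safe
    scaled[:, degenerate] = 0.0
    df = pd.DataFrame(scaled, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(df, "scaled")


def phospho_ratio(
    matrix: CountMatrix, panel: Panel, pseudocount: float = 1.0
) -> RatioMatrix:
    """Per-cell phospho/total protein ratio for every paired phospho epitope.

    ratio = (phospho + pseudocount) / (total + pseudocount); the pseudocount
    (default 1) guards against division by zero on sparse epitopes.
    """
    pairs = panel.phospho_pairs()
    if not pairs:
        raise QCError("panel has no phospho tags with a total_partner")
    cols = {}
    for phospho, total in pairs:
        num = matrix.values[phospho].to_numpy(dtype=float) + pseudocount
        den = matrix.values[total].to_numpy(dtype=float) + pseudocount
        cols[phospho] = num / den
    values = pd.DataFrame(cols, index=matrix.values.index)
    return RatioMatrix(values=values, pseudocount=pseudocount)
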