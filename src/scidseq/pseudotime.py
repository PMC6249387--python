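"""Marker-anchored pseudo-time ordering and per-epitope trend fitting.

Cells are ordered along differentiation by PCA on six anchor markers with
known directionality in epidermal differentiation — the basal markers ITGB1,
ITGA6 and TP63 fall, while the differentiation markers NICD, KLF4 and TGM1
rise. The first principal component of the 0-1-scaled marker sub-matrix
captures this axis; its sign is fixed so pseudo-time increases with the
designated up-marker (default TGM1), then min-max scaled to [0, 1]. Cells are
ranked, grouped into consecutive 10-cell bins to smooth single-cell noise,
and every epitope's bin means are fit with a third-order polynomial.

PCA runs on the already min-max-scaled marker columns, mean-centered but not
re-standardized to unit variance: the 0-1 scaling is the equalization step,
so a further standardization would double-correct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from sklearn.decomposition import PCA

from .demux import CountMatrix

DEFAULT_MARKERS = ("ITGB1", "ITGA6", "TP63", "NICD", "KLF4", "TGM1")
DEFAULT_UP_MARKER = "TGM1"
DEFAULT_DOWN_MARKER = "ITGB1"


@dataclass
class PseudotimeResult:
    """Per-cell pseudo-time with the PCA context that produced it."""

    marker_names: list[str]
    pc_variance_explained: np.ndarray
    pc1_score: pd.Series
    pseudotime: pd.Series
    rank: pd.Series
    bin_id: pd.Series
    orientation_flipped: bool
    orientation_ambiguous: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pc1_score": self.pc1_score,
                "pseudotime": self.pseudotime,
                "rank": self.rank,
                "bin_id": self.bin_id,
            }
        )


@dataclass
class TrendFit:
    """Cubic trend of one epitope over binned pseudo-time.

    ``coefficients`` are in ascending degree order (c0 + c1 t + c2 t^2 + c3 t^3),
    fit by ordinary least squares on the bin means. ``r_squared`` is clipped
    at 0 for pathological fits.
    """

    antibody_name: str
    bin_centers: np.ndarray
    bin_means: np.ndarray
    coefficients: np.ndarray
    r_squared: float

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return npoly.polyval(t, self.coefficients)

    @property
    def direction(self) -> int:
        """Sign of the fitted trend over [0, 1]: value at 1 minus value at 0."""
        return int(np.sign(self.predict(1.0) - self.predict(0.0)))


def marker_pca(
    matrix: CountMatrix, markers: list[str] | tuple[str, ...] = DEFAULT_MARKERS
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA on the cells × markers sub-matrix.

    Returns per-cell scores for all components and the variance fractions.
    Columns are mean-centered only (see module docstring).
    """
    missing = [m for m in markers if m not in matrix.values.columns]
    if missing:
        raise KeyError(f"marker(s) absent from matrix: {missing}")
    sub = matrix.values[list(markers)].to_numpy(dtype=float)
    n_cells, n_markers = sub.shape
    if n_cells < n_markers + 1:
        raise ValueError(
            f"need at least {n_markers + 1} cells for PCA on {n_markers} markers, "
            f"got {n_cells}"
        )
    pca = PCA(n_components=n_markers, svd_solver="full")
    scores = pca.fit_transform(sub)
    score_df = pd.DataFrame(
        scores,
        index=matrix.values.index,
        columns=[f"PC{i + 1}" for i in range(n_markers)],
    )
    return score_df, pca.explained_variance_ratio_


def orient_and_scale(
    pc1_score: pd.Series,
    matrix: CountMatrix,
    up_marker: str = DEFAULT_UP_MARKER,
    down_marker: str = DEFAULT_DOWN_MARKER,
) -> tuple[pd.Series, bool, bool]:
    """Fix PC1's sign and rescale to a [0, 1] pseudo-time.

    The sign is chosen so pseudo-time correlates positively with the
    up-marker; when that correlation is zero, the tie is broken toward a
    negative correlation with the down-marker. Returns (pseudotime,
    flipped, ambiguous).
    """
    for m in (up_marker, down_marker):
        if m not in matrix.values.columns:
            raise KeyError(f"orientation marker {m!r} absent from matrix")
    scores = pc1_score.to_numpy(dtype=float)
    up = matrix.values[up_marker].to_numpy(dtype=float)
    down = matrix.values[down_marker].to_numpy(dtype=float)

    def _corr(x: np.ndarray, y: np.ndarray) -> float:
        if np.std(x) == 0 or np.std(y) == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    c_up = _corr(scores, up)
    flipped = False
    ambiguous = False
    if c_up < 0:
        flipped = True
    elif c_up == 0:
        c_down = _corr(scores, down)
        if c_down > 0:
            flipped = True
        elif c_down == 0:
            ambiguous = True
            warnings.warn("pseudotime orientation ambiguous: both marker correlations are zero")
    oriented = -scores if flipped else scores
    lo, hi = oriented.min(), oriented.max()
    if hi > lo:
        pt = (oriented - lo) / (hi - lo)
    else:
        pt = np.zeros_like(oriented)
    return pd.Series(pt, index=pc1_score.index, name="pseudotime"), flipped, ambiguous


def bin_cells(pseudotime: pd.Series, bin_size: int = 10) -> pd.Series:
    """Assign rank-ordered cells to consecutive non-overlapping bins.

    Cells are sorted by pseudo-time (ties broken by position for
    determinism) and grouped into bins of ``bin_size``. A trailing remainder
    smaller than ``bin_size/2`` is merged into the previous bin; a larger
    remainder stays its own bin.
    """
    if bin_size < 2:
        raise ValueError("bin_size must be >= 2")
    n = len(pseudotime)
    order = np.argsort(pseudotime.to_numpy(), kind="stable")
    if n < bin_size:
        warnings.warn(f"fewer cells ({n}) than bin_size ({bin_size}); single bin")
        return pd.Series(np.zeros(n, dtype=int), index=pseudotime.index, name="bin_id")
    bins = np.empty(n, dtype=int)
    for rank, idx in enumerate(order):
        bins[idx] = rank // bin_size
    n_full_bins = n // bin_size
    remainder = n - n_full_bins * bin_size
    if remainder and remainder < bin_size / 2:
        bins[bins == n_full_bins] = n_full_bins - 1
    return pd.Series(bins, index=pseudotime.index, name="bin_id")


def rank_cells(pseudotime: pd.Series) -> pd.Series:
    """Dense 0..n-1 rank of cells by pseudo-time (stable for ties)."""
    order = np.argsort(pseudotime.to_numpy(), kind="stable")
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(len(order))
    return pd.Series(ranks, index=pseudotime.index, name="rank")


def compute_pseudotime(
    matrix: CountMatrix,
    markers: list[str] | tuple[str, ...] = DEFAULT_MARKERS,
    up_marker: str = DEFAULT_UP_MARKER,
    down_marker: str = DEFAULT_DOWN_MARKER,
    bin_size: int = 10,
) -> PseudotimeResult:
    """Full pseudo-time pipeline: marker PCA → orient/scale → rank → bin."""
    if matrix.state != "scaled":
        raise ValueError(f"pseudotime expects a scaled matrix, got {matrix.state!r}")
    scores, var = marker_pca(matrix, markers)
    pc1 = scores["PC1"]
    pt, flipped, ambiguous = orient_and_scale(pc1, matrix, up_marker, down_marker)
    return PseudotimeResult(
        marker_names=list(markers),
        pc_variance_explained=var,
        pc1_score=pc1,
        pseudotime=pt,
        rank=rank_cells(pt),
        bin_id=bin_cells(pt, bin_size),
        orientation_flipped=flipped,
        orientation_ambiguous=ambiguous,
    )


def fit_trend(
    bin_centers: np.ndarray, bin_means: np.ndarray, degree: int = 3,
    antibody_name: str = "",
) -> TrendFit:
    """Ordinary least-squares polynomial fit of bin means over pseudo-time."""
    bin_centers = np.asarray(bin_centers, dtype=float)
    bin_means = np.asarray(bin_means, dtype=float)
    if len(bin_centers) < degree + 1:
        raise ValueError(
            f"{len(bin_centers)} bins cannot support degree {degree}; "
            f"use degree <= {len(bin_centers) - 1}"
        )
    coeffs = npoly.polyfit(bin_centers, bin_means, degree)
    fitted = npoly.polyval(bin_centers, coeffs)
    ss_res = float(np.sum((bin_means - fitted) ** 2))
    ss_tot = float(np.sum((bin_means - bin_means.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return TrendFit(
        antibody_name=antibody_name,
        bin_centers=bin_centers,
        bin_means=bin_means,
        coefficients=coeffs,
        r_squared=r2,
    )


def trend_all(
    matrix: CountMatrix,
    result: PseudotimeResult,
    degree: int = 3,
    extra_columns: pd.DataFrame | None = None,
) -> dict[str, TrendFit]:
    """Bin means and cubic trend for every antibody column (plus optional
    extra columns such as phospho/total ratios, aligned on cell index)."""
    values = matrix.values
    if extra_columns is not None:
        values = pd.concat([values, extra_columns.loc[values.index]], axis=1)
    bins = result.bin_id
    centers = result.pseudotime.groupby(bins).mean().to_numpy()
    fits: dict[str, TrendFit] = {}
    for name in values.columns:
        means = values[name].groupby(bins).mean().to_numpy()
        fits[name] = fit_trend(centers, means, degree=degree, antibody_name=name)
    return fits


def trends_frame(fits: dict[str, TrendFit]) -> pd.DataFrame:
    """Tabular view of trend fits (one row per antibody)."""
    return pd.DataFrame(
        {
            "antibody_name": list(fits),
            "c0": [f.coefficients[0] for f in fits.values()],
            "c1": [f.coefficients[1] for f in fits.values()],
            "c2": [f.coefficients[2] for f in fits.values()],
            "c3": [f.coefficients[3] if len(f.coefficients) > 3 else 0.0 for f in fits.values()],
            "r_squared": [f.r_squared for f in fits.values()],
            "direction": [f.direction for f in fits.values()],
        }
    )
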