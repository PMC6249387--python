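"""Differential epitope testing between sorted populations.

Each antibody's per-cell distribution is compared between the two FACS gates
(ITGB1+ vs ITGB1low) with the two-sample Kolmogorov-Smirnov test: D is the
maximal gap between the empirical CDFs, with a two-sided p-value from the
asymptotic Kolmogorov distribution (effective-n corrected). Epitopes with
p below the threshold (default 0.001) are flagged dynamic; a pathway is
reported concordant when at least two of its significant antibodies trend in
the same direction over pseudo-time.

No multiple-testing correction is applied on the primary selection path (the
raw p < 0.001 rule); Benjamini-Hochberg q-values are reported as an
informational column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .demux import CountMatrix
from .pseudotime import TrendFit


@dataclass
class KSResult:
    antibody_name: str
    d_statistic: float
    p_value: float
    n_a: int
    n_b: int
    significant: bool
    pathway_group: str | None = None
    q_value: float | None = None
    trend_direction: int | None = None


def ks_two_sample(
    values_a: np.ndarray, values_b: np.ndarray, method: str = "asymp"
) -> tuple[float, float]:
    """Two-sample K-S test: D = sup_x |ECDF_a(x) - ECDF_b(x)| and two-sided p.

    ``method`` is ``asymp`` (Kolmogorov distribution with the standard
    sqrt(n_a*n_b/(n_a+n_b)) effective-n correction; default) or ``exact``
    (permutation-free exact distribution, sensible for n_a*n_b <= 10,000).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if method == "exact" and len(a) * len(b) > 10_000:
        raise ValueError("exact method limited to n_a * n_b <= 10,000")
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def select_dynamic(
    matrix: CountMatrix,
    gate_labels: pd.Series | None = None,
    alpha: float = 0.001,
    trends: dict[str, TrendFit] | None = None,
    method: str = "asymp",
) -> tuple[list[KSResult], pd.DataFrame]:
    """K-S test every antibody between the two gate populations.

    ``gate_labels`` defaults to the matrix's own ``gate_label`` metadata.
    Returns all per-antibody results and a concordance table flagging
    pathways where >= 2 significant antibodies share a pseudo-time trend
    direction (directions from ``trends`` when supplied).
    """
    if gate_labels is None:
        gate_labels = matrix.row_meta["gate_label"]
    gate_labels = gate_labels.loc[matrix.values.index]
    groups = [g for g in pd.unique(gate_labels) if g != "none"]
    if len(groups) != 2:
        raise ValueError(f"need exactly two gate labels, found {list(groups)}")
    ga, gb = groups
    mask_a = (gate_labels == ga).to_numpy()
    mask_b = (gate_labels == gb).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(
            f"each gate needs >= 2 cells (got {ga}: {mask_a.sum()}, {gb}: {mask_b.sum()})"
        )

    results: list[KSResult] = []
    for name in matrix.values.columns:
        col = matrix.values[name].to_numpy(dtype=float)
        d, p = ks_two_sample(col[mask_a], col[mask_b], method=method)
        pathway = matrix.col_meta.loc[name].get("pathway_group")
        if pd.isna(pathway) or pathway == "":
            pathway = None
        direction = trends[name].direction if trends and name in trends else None
        results.append(
            KSResult(
                antibody_name=name,
                d_statistic=d,
                p_value=p,
                n_a=int(mask_a.sum()),
                n_b=int(mask_b.sum()),
                significant=bool(p < alpha),
                pathway_group=pathway,
                trend_direction=direction,
            )
        )
    qs = benjamini_hochberg(np.array([r.p_value for r in results]))
    for r, q in zip(results, qs):
        r.q_value = float(q)

    concordance = _pathway_concordance(results)
    return results, concordance


def _pathway_concordance(results: list[KSResult]) -> pd.DataFrame:
    rows = []
    pathways = sorted({r.pathway_group for r in results if r.pathway_group})
    for pw in pathways:
        sig = [r for r in results if r.pathway_group == pw and r.significant]
        dirs = {r.trend_direction for r in sig if r.trend_direction is not None}
        concordant = len(sig) >= 2 and len(dirs) == 1 and dirs != {None}
        rows.append(
            {
                "pathway_group": pw,
                "n_significant": len(sig),
                "concordant": concordant,
                "direction": dirs.pop() if concordant else 0,
            }
        )
    return pd.DataFrame(rows, columns=["pathway_group", "n_significant", "concordant", "direction"])


def results_frame(results: list[KSResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "antibody_name": [r.antibody_name for r in results],
            "d_statistic": [r.d_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "n_a": [r.n_a for r in results],
            "n_b": [r.n_b for r in results],
            "significant": [r.significant for r in results],
            "pathway_group": [r.pathway_group or "" for r in results],
            "trend_direction": [
                r.trend_direction if r.trend_direction is not None else 0
                for r in results
            ],
        }
    )
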