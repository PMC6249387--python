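"""FASTQ demultiplexing and UMI counting.

Reads carry three in-line segments — a well barcode identifying the sorted
plate well (hence the single cell), a 10-nt antibody barcode identifying the
antibody-DNA conjugate, and a 15-nt UMI labelling the individual conjugate
molecule. This module extracts the segments, assigns them against the plate
and panel whitelists with optional single-mismatch error correction, and
collapses reads per (well, antibody) to distinct-UMI counts.

Ambiguous barcode matches (two whitelist entries tied at the minimal
qualifying distance) are rejected, never guessed: barcode sets are designed
with discrete, well-separated codes, so ambiguity signals an error beyond the
design tolerance.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import Panel, PlateLayout, ReadLayout, hamming

VALID_STATES = ("raw", "filtered", "subsampled", "scaled", "ratio")


class DemuxConfigError(ValueError):
    """Panel / mismatch-tolerance incompatibility detected before streaming."""


@dataclass(frozen=True)
class AssignedRead:
    """A read resolved to a well and an antibody, with its UMI."""

    well_id: str
    antibody_name: str
    umi: str
    n_mismatches_ab: int = 0
    n_mismatches_well: int = 0


@dataclass
class DemuxReport:
    """Per-run read accounting. Tallies partition ``n_reads_total``:
    every read is too-short, antibody-unassigned, well-unassigned, or
    assigned (checked by :meth:`validate`)."""

    n_reads_total: int = 0
    n_too_short: int = 0
    n_ab_unassigned: int = 0
    n_well_unassigned: int = 0
    n_assigned: int = 0
    n_ab_corrected: int = 0
    n_well_corrected: int = 0
    per_well: dict[str, int] = field(default_factory=dict)
    per_antibody: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        parts = (
            self.n_too_short
            + self.n_ab_unassigned
            + self.n_well_unassigned
            + self.n_assigned
        )
        if parts != self.n_reads_total:
            raise AssertionError(
                f"demux tallies {parts} do not partition {self.n_reads_total} reads"
            )

    def to_dict(self) -> dict:
        return {
            "n_reads_total": self.n_reads_total,
            "n_too_short": self.n_too_short,
            "n_ab_unassigned": self.n_ab_unassigned,
            "n_well_unassigned": self.n_well_unassigned,
            "n_assigned": self.n_assigned,
            "n_ab_corrected": self.n_ab_corrected,
            "n_well_corrected": self.n_well_corrected,
            "per_well": dict(self.per_well),
            "per_antibody": dict(self.per_antibody),
        }


@dataclass
class CountMatrix:
    """Wells/cells × antibodies UMI count matrix with metadata.

    ``values`` is a DataFrame (rows = wells indexed by well_id, columns =
    antibody names); ``row_meta`` carries well_type, gate_label and
    total_umis; ``col_meta`` carries the panel tag fields. ``state`` tracks
    processing: raw → filtered → subsampled → scaled (or ratio).
    """

    values: pd.DataFrame
    row_meta: pd.DataFrame
    col_meta: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if not self.values.index.equals(self.row_meta.index):
            raise ValueError("row metadata index does not match matrix rows")
        if not self.values.columns.equals(self.col_meta.index):
            raise ValueError("column metadata index does not match matrix columns")
        arr = self.values.to_numpy()
        if self.state in ("raw", "filtered", "subsampled"):
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(f"{self.state} matrix must hold integers")
            if (arr < 0).any():
                raise ValueError("counts must be non-negative")
        elif self.state == "scaled":
            if arr.size and (arr.min() < -1e-12 or arr.max() > 1 + 1e-12):
                raise ValueError("scaled values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, state: str) -> "CountMatrix":
        """New matrix with the same column metadata, possibly fewer rows."""
        return CountMatrix(
            values=values,
            row_meta=self.row_meta.loc[values.index].copy(),
            col_meta=self.col_meta.copy(),
            state=state,
        )

    def cells(self) -> "CountMatrix":
        keep = self.row_meta.index[self.row_meta["well_type"] == "cell"]
        return self.with_values(self.values.loc[keep], self.state)


class BarcodeMatcher:
    """Error-tolerant matching of an observed sequence against a whitelist.

    Exact matches resolve by hash lookup. Within ``max_mismatch``, the unique
    nearest entry is returned; ties at the minimal qualifying distance are
    rejected (``None``). For ``max_mismatch == 1`` a precomputed
    single-substitution neighbour table makes correction O(1) per read.
    """

    def __init__(self, whitelist: Iterable[str], max_mismatch: int = 0):
        self.whitelist = list(whitelist)
        if not self.whitelist:
            raise ValueError("empty whitelist")
        lens = {len(b) for b in self.whitelist}
        if len(lens) != 1:
            raise ValueError(f"whitelist entries have mixed lengths {sorted(lens)}")
        self.length = lens.pop()
        self.max_mismatch = int(max_mismatch)
        self._exact = {b: b for b in self.whitelist}
        self._neighbors: dict[str, str | None] | None = None
        if self.max_mismatch == 1:
            self._neighbors = self._build_neighbors()

    def _build_neighbors(self) -> dict[str, str | None]:
        table: dict[str, str | None] = {}
        for bc in self.whitelist:
            for i in range(self.length):
                for base in "ACGT":
                    if base == bc[i]:
                        continue
                    var = bc[:i] + base + bc[i + 1 :]
                    if var in self._exact:
                        continue  # exact entries win
                    # two whitelist entries one mismatch away: ambiguous
                    table[var] = None if var in table else bc
        return table

    def match(self, observed: str) -> tuple[str, int] | None:
        """Return (whitelist entry, distance) or None for no/ambiguous match."""
        if len(observed) != self.length:
            raise ValueError(
                f"observed length {len(observed)} != whitelist length {self.length}"
            )
        hit = self._exact.get(observed)
        if hit is not None:
            return hit, 0
        if self.max_mismatch == 0:
            return None
        if self._neighbors is not None:
            hit = self._neighbors.get(observed)
            return (hit, 1) if hit is not None else None
        # general fallback: full Hamming scan, reject minimal-distance ties
        best, best_d, tied = None, self.max_mismatch + 1, False
        for bc in self.whitelist:
            d = hamming(observed, bc)
            if d < best_d:
                best, best_d, tied = bc, d, False
            elif d == best_d:
                tied = True
        if best is None or best_d > self.max_mismatch or tied:
            return None
        return best, best_d


def match_barcode(
    observed: str, whitelist: Iterable[str], max_mismatch: int = 0
) -> tuple[str, int] | None:
    """One-shot barcode match; see :class:`BarcodeMatcher`."""
    return BarcodeMatcher(whitelist, max_mismatch).match(observed)


def extract_segments(
    read_sequence: str, layout: ReadLayout
) -> tuple[str, str, str] | None:
    """Extract (well_bc, ab_bc, umi) from a read, or None when too short."""
    if len(read_sequence) < layout.min_read_length:
        return None
    wo, wl = layout.well_bc
    ao, al = layout.ab_bc
    uo, ul = layout.umi
    return (
        read_sequence[wo : wo + wl],
        read_sequence[ao : ao + al],
        read_sequence[uo : uo + ul],
    )


def open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO:
    """Open plain or gzipped text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a (possibly gzipped) FASTQ file."""
    with open_maybe_gzip(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq


def assign_reads(
    reads: Iterable[str],
    layout: ReadLayout,
    panel: Panel,
    plate: PlateLayout,
    max_mismatch_ab: int = 1,
    max_mismatch_well: int = 1,
) -> tuple[list[AssignedRead], DemuxReport]:
    """Assign each read sequence to a (well, antibody, UMI) triple.

    Raises :class:`DemuxConfigError` before streaming when the panel's
    minimum pairwise barcode distance cannot support the requested antibody
    mismatch tolerance (unambiguous correction needs ``d_min >= 2m + 1``).
    """
    if max_mismatch_ab > 0 and panel.min_pairwise_distance < 2 * max_mismatch_ab + 1:
        raise DemuxConfigError(
            f"panel min pairwise distance {panel.min_pairwise_distance} cannot "
            f"support max_mismatch_ab={max_mismatch_ab} "
            f"(needs >= {2 * max_mismatch_ab + 1}); use exact matching"
        )
    ab_matcher = BarcodeMatcher(panel.barcodes, max_mismatch_ab)
    well_matcher = BarcodeMatcher(plate.barcodes, max_mismatch_well)
    ab_names = {t.barcode: t.antibody_name for t in panel}
    well_ids = {bc: w.well_id for bc, w in plate.wells.items()}

    report = DemuxReport()
    assigned: list[AssignedRead] = []
    for seq in reads:
        report.n_reads_total += 1
        segs = extract_segments(seq, layout)
        if segs is None:
            report.n_too_short += 1
            continue
        well_bc, ab_bc, umi = segs
        ab_hit = ab_matcher.match(ab_bc)
        if ab_hit is None:
            report.n_ab_unassigned += 1
            continue
        well_hit = well_matcher.match(well_bc)
        if well_hit is None:
            report.n_well_unassigned += 1
            continue
        ab, d_ab = ab_hit
        well, d_well = well_hit
        name = ab_names[ab]
        wid = well_ids[well]
        report.n_assigned += 1
        if d_ab > 0:
            report.n_ab_corrected += 1
        if d_well > 0:
            report.n_well_corrected += 1
        report.per_well[wid] = report.per_well.get(wid, 0) + 1
        report.per_antibody[name] = report.per_antibody.get(name, 0) + 1
        assigned.append(AssignedRead(wid, name, umi, d_ab, d_well))
    report.validate()
    return assigned, report


def _collapse_directional(umis: set[str]) -> int:
    """Count UMIs after merging single-mismatch neighbours (directional-style:
    a UMI is absorbed into any already-kept UMI within Hamming distance 1)."""
    kept: list[str] = []
    for u in sorted(umis):
        if not any(hamming(u, k) <= 1 for k in kept):
            kept.append(u)
    return len(kept)


def count_umis(
    assigned: Iterable[AssignedRead],
    panel: Panel,
    plate: PlateLayout,
    umi_collapse: str = "exact",
) -> CountMatrix:
    """Collapse assigned reads to distinct-UMI counts per (well, antibody).

    The matrix always has one row per plate well (empty wells retained for
    background QC) and one column per panel tag, regardless of which were
    observed. ``umi_collapse`` is ``exact`` (identity; default) or
    ``directional`` (additionally merges single-mismatch UMI neighbours).
    """
    if umi_collapse not in ("exact", "directional"):
        raise ValueError(f"unknown umi_collapse mode {umi_collapse!r}")
    sets: dict[tuple[str, str], set[str]] = {}
    for r in assigned:
        sets.setdefault((r.well_id, r.antibody_name), set()).add(r.umi)

    well_ids = plate.well_ids()
    names = panel.names
    counts = np.zeros((len(well_ids), len(names)), dtype=np.int64)
    widx = {w: i for i, w in enumerate(well_ids)}
    aidx = {a: j for j, a in enumerate(names)}
    for (w, a), umis in sets.items():
        if w not in widx or a not in aidx:
            raise KeyError(f"assigned read references unknown well/antibody ({w}, {a})")
        n = len(umis) if umi_collapse == "exact" else _collapse_directional(umis)
        counts[widx[w], aidx[a]] = n

    values = pd.DataFrame(
        counts, index=pd.Index(well_ids, name="well_id"), columns=names
    )
    row_meta = plate.meta_frame()
    row_meta["total_umis"] = values.sum(axis=1)
    col_meta = panel.to_frame().set_index("antibody_name")
    return CountMatrix(values=values, row_meta=row_meta, col_meta=col_meta, state="raw")


def merge_replicate_barcodes(
    matrix: CountMatrix, panel: Panel, merge: bool = False
) -> tuple[pd.DataFrame, CountMatrix | None]:
    """Replicate-barcode concordance and optional merged matrix.

    For every replicate group (several barcodes conjugated to the same
    antibody), computes the Pearson correlation across cells for every pair
    of member columns. When ``merge`` is true, also returns a matrix where
    each group's member columns are summed into one column named after the
    group.
    """
    import warnings

    groups = panel.replicate_groups()
    if not groups:
        raise ValueError("panel has no replicate groups")
    rows = []
    for group, members in groups.items():
        if len(members) < 2:
            warnings.warn(f"replicate group {group!r} has <2 members; skipped")
            continue
        for a, b in itertools.combinations(members, 2):
            x = matrix.values[a].to_numpy(dtype=float)
            y = matrix.values[b].to_numpy(dtype=float)
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"replicate_group": group, "member_a": a, "member_b": b, "pearson_r": r})
    corr = pd.DataFrame(rows, columns=["replicate_group", "member_a", "member_b", "pearson_r"])

    merged = None
    if merge:
        grouped = set()
        cols: dict[str, pd.Series] = {}
        order: list[str] = []
        member_to_group = {
            m: g for g, ms in groups.items() if len(ms) >= 2 for m in ms
        }
        for name in matrix.values.columns:
            g = member_to_group.get(name)
            if g is None:
                cols[name] = matrix.values[name]
                order.append(name)
            elif g not in grouped:
                cols[g] = matrix.values[groups[g]].sum(axis=1)
                order.append(g)
                grouped.add(g)
        values = pd.DataFrame({k: cols[k] for k in order})
        col_meta = pd.DataFrame(index=pd.Index(order, name="antibody_name"))
        for field_ in matrix.col_meta.columns:
            col_meta[field_] = [
                matrix.col_meta.loc[groups[n][0], field_]
                if n in groups and len(groups[n]) >= 2
                else matrix.col_meta.loc[n, field_]
                for n in order
            ]
        col_meta["barcode"] = ""  # merged columns have no single barcode
        merged = CountMatrix(
            values=values, row_meta=matrix.row_meta.copy(), col_meta=col_meta,
            state=matrix.state,
        )
    return corr, merged
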