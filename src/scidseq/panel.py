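"""Antibody panels, barcode whitelists, read layouts and plate layouts.

These are the shared domain objects of the pipeline: an :class:`AntibodyTag`
describes one antibody-DNA conjugate (the 10-nt barcode identifies the epitope
in sequencing reads), a :class:`Panel` is the validated collection of tags
used in one experiment, a :class:`ReadLayout` locates the well barcode,
antibody barcode and UMI segments inside a read, and a :class:`PlateLayout`
maps well barcodes to sorted-cell versus empty wells.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

AB_BARCODE_LEN = 10
UMI_LEN = 15

_VALID_EPITOPE_CLASSES = {"total", "phospho", "ligand", "receptor", "other"}
_VALID_WELL_TYPES = {"cell", "empty"}
_VALID_GATES = {"ITGB1+", "ITGB1low", "none"}

_ACGT = frozenset("ACGT")


class PanelError(ValueError):
    """Raised when a panel or layout fails validation."""


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class AntibodyTag:
    """One antibody-DNA conjugate.

    Parameters
    ----------
    antibody_name:
        Human-readable antibody label, unique within a panel.
    barcode:
        10-nt DNA barcode identifying the antibody in reads.
    epitope_class:
        One of ``total``, ``phospho``, ``ligand``, ``receptor``, ``other``.
    total_partner:
        For phospho epitopes, the name of the matching total-protein tag
        (enables phospho/total ratio computation).
    pathway_group:
        Free-text pathway label (e.g. ``BMP``, ``WNT``, ``JAK-STAT``).
    replicate_group:
        Label grouping several barcodes conjugated to the same antibody,
        used for replicate-barcode concordance analysis.
    """

    antibody_name: str
    barcode: str
    epitope_class: str = "other"
    total_partner: str | None = None
    pathway_group: str | None = None
    replicate_group: str | None = None

    def __post_init__(self) -> None:
        if len(self.barcode) != AB_BARCODE_LEN:
            raise PanelError(
                f"tag {self.antibody_name!r}: barcode {self.barcode!r} has "
                f"length {len(self.barcode)}, expected {AB_BARCODE_LEN}"
            )
        bad = set(self.barcode) - _ACGT
        if bad:
            raise PanelError(
                f"tag {self.antibody_name!r}: non-ACGT characters {sorted(bad)} in barcode"
            )
        if self.epitope_class not in _VALID_EPITOPE_CLASSES:
            raise PanelError(
                f"tag {self.antibody_name!r}: unknown epitope_class "
                f"{self.epitope_class!r} (expected one of {sorted(_VALID_EPITOPE_CLASSES)})"
            )


@dataclass
class Panel:
    """Ordered, validated collection of antibody tags.

    ``min_pairwise_distance`` is the minimum Hamming distance over all
    barcode pairs; error-tolerant assignment at ``max_mismatch`` requires
    ``min_pairwise_distance >= 2 * max_mismatch + 1`` so corrections are
    unambiguous.
    """

    tags: list[AntibodyTag]
    min_pairwise_distance: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.tags:
            raise PanelError("panel is empty")
        seen_bc: dict[str, str] = {}
        seen_names: set[str] = set()
        for tag in self.tags:
            if tag.barcode in seen_bc:
                raise PanelError(
                    f"duplicate barcode {tag.barcode}: tags "
                    f"{seen_bc[tag.barcode]!r} and {tag.antibody_name!r}"
                )
            seen_bc[tag.barcode] = tag.antibody_name
            if tag.antibody_name in seen_names:
                raise PanelError(f"duplicate antibody_name {tag.antibody_name!r}")
            seen_names.add(tag.antibody_name)
        totals = {t.antibody_name for t in self.tags if t.epitope_class == "total"}
        for tag in self.tags:
            if tag.total_partner is not None and tag.total_partner not in totals:
                raise PanelError(
                    f"tag {tag.antibody_name!r}: total_partner "
                    f"{tag.total_partner!r} is not a 'total' tag in this panel"
                )
        self.min_pairwise_distance = self._min_distance()

    def _min_distance(self) -> int:
        if len(self.tags) < 2:
            return AB_BARCODE_LEN
        return min(
            hamming(a.barcode, b.barcode)
            for a, b in itertools.combinations(self.tags, 2)
        )

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)

    @property
    def barcodes(self) -> list[str]:
        return [t.barcode for t in self.tags]

    @property
    def names(self) -> list[str]:
        return [t.antibody_name for t in self.tags]

    def by_barcode(self) -> dict[str, AntibodyTag]:
        return {t.barcode: t for t in self.tags}

    def by_name(self) -> dict[str, AntibodyTag]:
        return {t.antibody_name: t for t in self.tags}

    def phospho_pairs(self) -> list[tuple[str, str]]:
        """(phospho_name, total_name) for every phospho tag with a partner."""
        return [
            (t.antibody_name, t.total_partner)
            for t in self.tags
            if t.epitope_class == "phospho" and t.total_partner is not None
        ]

    def replicate_groups(self) -> dict[str, list[str]]:
        """Map replicate_group label -> member antibody names (panel order)."""
        groups: dict[str, list[str]] = {}
        for t in self.tags:
            if t.replicate_group is not None:
                groups.setdefault(t.replicate_group, []).append(t.antibody_name)
        return groups

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "antibody_name": [t.antibody_name for t in self.tags],
                "barcode": [t.barcode for t in self.tags],
                "epitope_class": [t.epitope_class for t in self.tags],
                "total_partner": [t.total_partner for t in self.tags],
                "pathway_group": [t.pathway_group for t in self.tags],
                "replicate_group": [t.replicate_group for t in self.tags],
            }
        )


@dataclass(frozen=True)
class ReadLayout:
    """Segment coordinates inside a single-end read (0-based, half-open).

    Each segment is an ``(offset, length)`` pair. The antibody barcode is
    always 10 nt and the UMI always 15 nt; the well barcode length is
    configurable (default 8 nt in the simulator).
    """

    well_bc: tuple[int, int]
    ab_bc: tuple[int, int]
    umi: tuple[int, int]
    min_read_length: int = 0

    def __post_init__(self) -> None:
        if self.ab_bc[1] != AB_BARCODE_LEN:
            raise PanelError(f"antibody barcode segment must be {AB_BARCODE_LEN} nt")
        if self.umi[1] != UMI_LEN:
            raise PanelError(f"UMI segment must be {UMI_LEN} nt")
        for name, (off, ln) in self.segments().items():
            if off < 0 or ln <= 0:
                raise PanelError(f"segment {name}: invalid (offset={off}, length={ln})")
        ends = max(off + ln for off, ln in self.segments().values())
        if self.min_read_length < ends:
            object.__setattr__(self, "min_read_length", ends)
        if self._overlapping():
            raise PanelError("read layout segments overlap")

    def segments(self) -> dict[str, tuple[int, int]]:
        return {"well_bc": self.well_bc, "ab_bc": self.ab_bc, "umi": self.umi}

    def _overlapping(self) -> bool:
        ivals = sorted((off, off + ln) for off, ln in self.segments().values())
        return any(ivals[i][1] > ivals[i + 1][0] for i in range(len(ivals) - 1))

    def to_json(self) -> str:
        return json.dumps(
            {
                "well_bc": list(self.well_bc),
                "ab_bc": list(self.ab_bc),
                "umi": list(self.umi),
                "min_read_length": self.min_read_length,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReadLayout":
        d = json.loads(text)
        return cls(
            well_bc=tuple(d["well_bc"]),
            ab_bc=tuple(d["ab_bc"]),
            umi=tuple(d["umi"]),
            min_read_length=int(d.get("min_read_length", 0)),
        )


def validate_layout(layout: ReadLayout, read_length: int) -> bool:
    """True iff every segment fits within ``read_length`` (segments are
    guaranteed non-overlapping by construction)."""
    return all(off + ln <= read_length for off, ln in layout.segments().values())


@dataclass(frozen=True)
class Well:
    well_id: str
    well_type: str
    gate_label: str = "none"

    def __post_init__(self) -> None:
        if self.well_type not in _VALID_WELL_TYPES:
            raise PanelError(
                f"well {self.well_id!r}: well_type {self.well_type!r} "
                f"not in {sorted(_VALID_WELL_TYPES)}"
            )
        if self.gate_label not in _VALID_GATES:
            raise PanelError(
                f"well {self.well_id!r}: gate_label {self.gate_label!r} "
                f"not in {sorted(_VALID_GATES)}"
            )


@dataclass
class PlateLayout:
    """Mapping well_barcode -> :class:`Well` for one sorted plate."""

    wells: dict[str, Well]

    def __post_init__(self) -> None:
        if not any(w.well_type == "cell" for w in self.wells.values()):
            raise PanelError("plate layout has no cell wells")
        ids = [w.well_id for w in self.wells.values()]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate well_id in plate layout")

    @property
    def barcodes(self) -> list[str]:
        return list(self.wells)

    def well_ids(self, well_type: str | None = None) -> list[str]:
        return [
            w.well_id
            for w in self.wells.values()
            if well_type is None or w.well_type == well_type
        ]

    def meta_frame(self) -> pd.DataFrame:
        """Well metadata indexed by well_id, in plate order."""
        return pd.DataFrame(
            {
                "well_type": [w.well_type for w in self.wells.values()],
                "gate_label": [w.gate_label for w in self.wells.values()],
            },
            index=pd.Index([w.well_id for w in self.wells.values()], name="well_id"),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well_barcode": list(self.wells),
                "well_id": [w.well_id for w in self.wells.values()],
                "well_type": [w.well_type for w in self.wells.values()],
                "gate_label": [w.gate_label for w in self.wells.values()],
            }
        )


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a tab- or comma-delimited sheet with a header row."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def load_panel(path: str | Path) -> Panel:
    """Load and validate an antibody panel sheet.

    The sheet is tab- or comma-delimited with at least ``antibody_name``,
    ``barcode`` and ``epitope_class`` columns; ``total_partner``,
    ``pathway_group`` and ``replicate_group`` are optional. Empty cells mean
    "not set".
    """
    df = _read_table(path)
    required = {"antibody_name", "barcode", "epitope_class"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"{path}: missing panel columns {sorted(missing)}")
    dup = df["barcode"][df["barcode"].duplicated(keep=False)]
    if not dup.empty:
        rows = ", ".join(
            f"row {i + 2} ({df.loc[i, 'antibody_name']})" for i in dup.index
        )
        raise PanelError(f"{path}: duplicate barcode(s) {sorted(set(dup))}: {rows}")
    tags = []
    for i, row in df.iterrows():
        bad = set(row["barcode"]) - _ACGT
        if bad:
            raise PanelError(
                f"{path}, line {i + 2}: non-ACGT character(s) {sorted(bad)} "
                f"in barcode {row['barcode']!r}"
            )
        tags.append(
            AntibodyTag(
                antibody_name=row["antibody_name"],
                barcode=row["barcode"],
                epitope_class=row["epitope_class"],
                total_partner=row.get("total_partner") or None,
                pathway_group=row.get("pathway_group") or None,
                replicate_group=row.get("replicate_group") or None,
            )
        )
    return Panel(tags)


def save_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel sheet (TSV) that :func:`load_panel` reads back identically."""
    df = panel.to_frame().fillna("")
    df.to_csv(path, sep="\t", index=False)


def load_plate(path: str | Path) -> PlateLayout:
    """Load a plate layout sheet (well_barcode, well_id, well_type, gate_label)."""
    df = _read_table(path)
    required = {"well_barcode", "well_id", "well_type"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"{path}: missing plate columns {sorted(missing)}")
    if df["well_barcode"].duplicated().any():
        dups = sorted(set(df["well_barcode"][df["well_barcode"].duplicated()]))
        raise PanelError(f"{path}: duplicate well barcode(s) {dups}")
    wells = {}
    for _, row in df.iterrows():
        wells[row["well_barcode"]] = Well(
            well_id=row["well_id"],
            well_type=row["well_type"],
            gate_label=row.get("gate_label") or "none",
        )
    return PlateLayout(wells)


def save_plate(plate: PlateLayout, path: str | Path) -> None:
    plate.to_frame().to_csv(path, sep="\t", index=False)
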