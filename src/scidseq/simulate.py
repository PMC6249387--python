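"""Ground-truthed synthetic scID-seq experiments.

Emulates a plate-based single-cell antibody-barcode sequencing run: single
cells FACS-sorted into a 96-well-format plate (plus empty background wells),
stained with a panel of DNA-barcoded antibodies, preamplified (PCR
duplication), and sequenced with per-base substitution errors. Every cell
carries a latent differentiation time in [0, 1]; six anchor markers follow
logistic curves with staggered midpoints (ITGB1, ITGA6, TP63 fall; NICD,
KLF4, TGM1 rise), a few pathway antibodies are mildly dynamic, and the rest
are static. Molecule counts are negative-binomial around per-cell expected
means (overdispersion is the norm for molecular counts; the Poisson limit is
available via a large dispersion). Empty wells draw Poisson background at a
configured fraction of the cell signal.

All randomness flows from a single seed; identical configs give identical
outputs, which makes the simulator the pipeline's end-to-end oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import (
    AB_BARCODE_LEN,
    UMI_LEN,
    AntibodyTag,
    Panel,
    PlateLayout,
    ReadLayout,
    Well,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

MARKER_DIRECTIONS = {
    "ITGB1": "down",
    "ITGA6": "down",
    "TP63": "down",
    "NICD": "up",
    "KLF4": "up",
    "TGM1": "up",
}
# staggered midpoints spread over the trajectory create distinct kinetics
# per marker and keep every stretch of pseudo-time informative
MARKER_MIDPOINTS = {
    "ITGA6": 0.30,
    "NICD": 0.35,
    "ITGB1": 0.50,
    "KLF4": 0.55,
    "TP63": 0.70,
    "TGM1": 0.75,
}

DEFAULT_REPLICATE_ANTIBODIES = ("ITGA6", "ITGB1", "Actin", "TGM1", "RNApol2")

# pathway antibodies activated during differentiation, mirroring the
# JAK-STAT / WNT / BMP programs of differentiating keratinocytes
PATHWAY_ANTIBODIES = {
    "JAK-STAT": ["pJAK1", "pSTAT1", "pSTAT5"],
    "WNT": ["FZD3", "pLRP6", "pGSK3B"],
    "BMP": ["BMP2-4", "BMPR2", "pSMAD159"],
}


@dataclass(frozen=True)
class SimConfig:
    """Study design and noise model for one synthetic experiment.

    Defaults match the emulated plate design: 84 cell wells and 48 empty
    wells (one 132-well sort), a 69-antibody panel, background at 1% of the
    cell signal (100-fold separation), and a mean duplication of 2 extra PCR
    copies per molecule.
    """

    n_cell_wells: int = 84
    n_empty_wells: int = 48
    panel_size: int = 69
    mean_depth: int = 5000
    background_fraction: float = 0.01
    duplication_rate: float = 2.0
    error_rate: float = 0.001
    nb_dispersion: float = 10.0
    noise_sd: float = 0.25
    depth_sd: float = 0.3
    marker_fold_change: float = 8.0
    marker_steepness: float = 10.0
    gate_cut: float = 0.7
    well_bc_len: int = 8
    n_low_quality_cells: int = 0
    low_quality_factor: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cell_wells, self.panel_size, self.mean_depth) <= 0:
            raise ValueError("counts must be positive")
        if self.n_empty_wells < 0:
            raise ValueError("n_empty_wells must be >= 0")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")
        if not 0 <= self.error_rate <= 0.25:
            raise ValueError("error_rate must be in [0, 0.25]")
        if self.panel_size < len(MARKER_DIRECTIONS):
            raise ValueError(f"panel_size must be >= {len(MARKER_DIRECTIONS)}")


@dataclass
class SimTruth:
    """Ground truth emitted by :func:`simulate_truth`."""

    config: SimConfig
    panel: Panel
    plate: PlateLayout
    latent_time: pd.Series          # per cell well, in [0, 1]
    gate_label: pd.Series           # per cell well
    true_counts: pd.DataFrame       # all wells x antibodies, integer molecules
    mean_matrix: pd.DataFrame       # expected molecule counts (float)
    low_quality_wells: list[str] = field(default_factory=list)


def _random_barcodes(
    rng: np.random.Generator, n: int, length: int, min_distance: int = 3
) -> list[str]:
    """Greedy rejection sampling of barcodes with pairwise Hamming >= min_distance."""
    chosen: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise RuntimeError(
                f"cannot place {n} barcodes of length {length} at distance {min_distance}"
            )
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != c).sum()) >= min_distance for c in chosen):
            chosen.append(cand)
    return ["".join("ACGT"[b] for b in bc) for bc in chosen]


def _make_panel(rng: np.random.Generator, config: SimConfig) -> Panel:
    """Build a synthetic antibody panel: 6 trajectory markers, pathway
    antibodies with paired phospho/total epitopes, and static fillers."""
    names: list[tuple[str, str, str | None, str | None]] = []
    # (name, epitope_class, total_partner, pathway_group)
    for m in MARKER_DIRECTIONS:
        names.append((m, "other", None, None))
    for pw, abs_ in PATHWAY_ANTIBODIES.items():
        for ab in abs_:
            if ab.startswith("p"):
                total = ab[1:]
                names.append((total, "total", None, pw))
                names.append((ab, "phospho", total, pw))
            else:
                names.append((ab, "other", None, pw))
    for extra in ("Actin", "RNApol2"):
        names.append((extra, "other", None, None))
    # paired phospho/total fillers until 11 pairs exist, then plain fillers
    n_pairs = sum(1 for n in names if n[1] == "phospho")
    i = 1
    while len(names) + 2 <= config.panel_size and n_pairs < 11:
        names.append((f"Prot{i:02d}", "total", None, None))
        names.append((f"pProt{i:02d}", "phospho", f"Prot{i:02d}", None))
        n_pairs += 1
        i += 1
    j = 1
    while len(names) < config.panel_size:
        names.append((f"Ab{j:02d}", "other", None, None))
        j += 1
    names = names[: config.panel_size]
    barcodes = _random_barcodes(rng, len(names), AB_BARCODE_LEN, min_distance=3)
    tags = [
        AntibodyTag(
            antibody_name=nm, barcode=bc, epitope_class=cls,
            total_partner=tp, pathway_group=pw,
        )
        for (nm, cls, tp, pw), bc in zip(names, barcodes)
    ]
    return Panel(tags)


def _make_plate(rng: np.random.Generator, config: SimConfig) -> PlateLayout:
    n = config.n_cell_wells + config.n_empty_wells
    barcodes = _random_barcodes(rng, n, config.well_bc_len, min_distance=3)
    wells: dict[str, Well] = {}
    for i in range(config.n_cell_wells):
        wells[barcodes[i]] = Well(well_id=f"C{i + 1:03d}", well_type="cell")
    for i in range(config.n_empty_wells):
        wells[barcodes[config.n_cell_wells + i]] = Well(
            well_id=f"E{i + 1:03d}", well_type="empty"
        )
    return PlateLayout(wells)


def _logistic(t: np.ndarray, direction: str, midpoint: float, config: SimConfig) -> np.ndarray:
    """Smooth monotone profile in [1/fold, 1] (down) or rising to 1 (up)."""
    lo = 1.0 / config.marker_fold_change
    s = 1.0 / (1.0 + np.exp(-config.marker_steepness * (t - midpoint)))
    if direction == "down":
        s = 1.0 - s
    return lo + (1.0 - lo) * s


def _profiles(
    rng: np.random.Generator, panel: Panel, t: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Relative per-antibody intensity profiles over latent time.

    Returns a (n_cells, n_antibodies) array of unnormalized expected
    abundances: baseline (lognormal across antibodies) x time profile.
    """
    n_ab = len(panel)
    baseline = np.exp(rng.normal(0.0, 0.8, size=n_ab))
    profiles = np.empty((len(t), n_ab))
    for j, tag in enumerate(panel):
        name = tag.antibody_name
        if name in MARKER_DIRECTIONS:
            f = _logistic(t, MARKER_DIRECTIONS[name], MARKER_MIDPOINTS[name], config)
        elif tag.pathway_group is not None:
            # mildly dynamic: rises ~3-fold during differentiation
            mild = replace(config, marker_fold_change=3.0, marker_steepness=6.0)
            mid = float(rng.uniform(0.35, 0.75))
            f = _logistic(t, "up", mid, mild)
        else:
            f = np.ones_like(t)
        profiles[:, j] = baseline[j] * f
    return profiles


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw a plate design, latent trajectory, and true molecule counts."""
    rng = np.random.default_rng(config.seed)
    panel = _make_panel(rng, config)
    plate = _make_plate(rng, config)
    cell_ids = plate.well_ids("cell")
    empty_ids = plate.well_ids("empty")
    n_cells, n_ab = len(cell_ids), len(panel)

    t = rng.uniform(0.0, 1.0, size=n_cells)
    profiles = _profiles(rng, panel, t, config)
    # per-cell multiplicative noise on each antibody's expectation
    if config.noise_sd > 0:
        profiles = profiles * np.exp(
            rng.normal(0.0, config.noise_sd, size=profiles.shape)
        )
    # rescale each cell so its expected total is mean_depth (x depth variation)
    depth = config.mean_depth * np.exp(rng.normal(0.0, config.depth_sd, size=n_cells))
    low_quality: list[str] = []
    if config.n_low_quality_cells:
        idx = rng.choice(n_cells, size=config.n_low_quality_cells, replace=False)
        depth[idx] = config.mean_depth * config.low_quality_factor
        low_quality = [cell_ids[i] for i in sorted(idx)]
    means = profiles / profiles.sum(axis=1, keepdims=True) * depth[:, None]

    r = config.nb_dispersion
    cell_counts = rng.negative_binomial(r, r / (r + means))

    # empty wells: Poisson background proportional to the average composition
    comp = means.sum(axis=0) / means.sum()
    bg_mean = config.background_fraction * config.mean_depth * comp
    empty_counts = rng.poisson(bg_mean, size=(len(empty_ids), n_ab))

    all_ids = cell_ids + empty_ids
    counts = pd.DataFrame(
        np.vstack([cell_counts, empty_counts]).astype(np.int64),
        index=pd.Index(all_ids, name="well_id"),
        columns=panel.names,
    ).loc[plate.well_ids()]
    mean_df = pd.DataFrame(
        np.vstack([means, np.tile(bg_mean, (len(empty_ids), 1))]),
        index=pd.Index(all_ids, name="well_id"),
        columns=panel.names,
    ).loc[plate.well_ids()]

    latent = pd.Series(t, index=pd.Index(cell_ids, name="well_id"), name="latent_time")
    gate = pd.Series(
        np.where(t < config.gate_cut, "ITGB1+", "ITGB1low"),
        index=latent.index, name="gate_label",
    )
    # annotate the plate with gate labels for downstream group testing
    wells = {
        bc: Well(w.well_id, w.well_type, gate.get(w.well_id, "none"))
        for bc, w in plate.wells.items()
    }
    plate = PlateLayout(wells)
    return SimTruth(
        config=config,
        panel=panel,
        plate=plate,
        latent_time=latent,
        gate_label=gate,
        true_counts=counts,
        mean_matrix=mean_df,
        low_quality_wells=low_quality,
    )


def truth_count_matrix(truth: SimTruth) -> "CountMatrix":
    """The simulator's true molecule matrix as a raw :class:`CountMatrix`
    (the noiseless-demultiplexing oracle for the counting pipeline)."""
    from .demux import CountMatrix

    row_meta = truth.plate.meta_frame()
    row_meta["total_umis"] = truth.true_counts.sum(axis=1)
    return CountMatrix(
        values=truth.true_counts.copy(),
        row_meta=row_meta,
        col_meta=truth.panel.to_frame().set_index("antibody_name"),
        state="raw",
    )


def default_layout(well_bc_len: int = 8) -> ReadLayout:
    """Contiguous in-line layout: well barcode, antibody barcode, UMI."""
    return ReadLayout(
        well_bc=(0, well_bc_len),
        ab_bc=(well_bc_len, AB_BARCODE_LEN),
        umi=(well_bc_len + AB_BARCODE_LEN, UMI_LEN),
    )


def _distinct_umis(rng: np.random.Generator, n: int) -> list[str]:
    """n distinct random 15-nt UMIs (resampling the rare collision)."""
    umis: set[str] = set()
    while len(umis) < n:
        block = rng.integers(0, 4, size=(n - len(umis), UMI_LEN))
        for row in block:
            umis.add("".join("ACGT"[b] for b in row))
    out = sorted(umis)
    rng.shuffle(out)  # sorted-then-shuffled for determinism
    return out[:n]


def simulate_reads(
    truth: SimTruth,
    layout: ReadLayout | None = None,
    force_ab_mismatches: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Emit PCR-duplicated, error-bearing read sequences for every molecule.

    Every true molecule receives a distinct random UMI and is emitted
    ``1 + Poisson(duplication_rate)`` times; each emitted read suffers
    independent per-base substitutions at ``error_rate``.
    ``force_ab_mismatches`` additionally substitutes exactly that many
    positions of every read's antibody-barcode segment (for error-correction
    stress tests). Returns (shuffled read sequences, molecule truth table
    with one row per molecule: well_id, antibody_name, umi).
    """
    config = truth.config
    if layout is None:
        layout = default_layout(config.well_bc_len)
    if config.error_rate > 0 and truth.panel.min_pairwise_distance < 3:
        raise ValueError(
            "error injection requires panel barcodes at pairwise distance >= 3"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    well_bc = {w.well_id: bc for bc, w in truth.plate.wells.items()}
    ab_bc = {t.antibody_name: t.barcode for t in truth.panel}

    mol_well: list[str] = []
    mol_ab: list[str] = []
    mol_umi: list[str] = []
    mol_seq: list[str] = []
    counts = truth.true_counts
    for wid in counts.index:
        wbc = well_bc[wid]
        row = counts.loc[wid]
        for ab, n in row.items():
            n = int(n)
            if n == 0:
                continue
            umis = _distinct_umis(rng, n)
            base = wbc + ab_bc[ab]
            for u in umis:
                mol_well.append(wid)
                mol_ab.append(ab)
                mol_umi.append(u)
                mol_seq.append(base + u)
    molecules = pd.DataFrame(
        {"well_id": mol_well, "antibody_name": mol_ab, "umi": mol_umi}
    )

    copies = 1 + rng.poisson(config.duplication_rate, size=len(mol_seq))
    reads = [s for s, c in zip(mol_seq, copies) for _ in range(c)]

    if config.error_rate > 0 or force_ab_mismatches > 0:
        arr = np.frombuffer("".join(reads).encode(), dtype="S1").reshape(
            len(reads), -1
        ).copy()
        if config.error_rate > 0:
            mask = rng.random(arr.shape) < config.error_rate
            shifts = rng.integers(1, 4, size=int(mask.sum()))
            arr[mask] = _mutate(arr[mask], shifts)
        if force_ab_mismatches > 0:
            off, ln = layout.ab_bc
            pos = np.argsort(
                rng.random((len(reads), ln)), axis=1
            )[:, :force_ab_mismatches]
            for k in range(force_ab_mismatches):
                cols = off + pos[:, k]
                idx = (np.arange(len(reads)), cols)
                shifts = rng.integers(1, 4, size=len(reads))
                arr[idx] = _mutate(arr[idx], shifts)
        reads = [row.tobytes().decode() for row in arr]

    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]
    return reads, molecules


_CODE = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _mutate(bases: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Substitute each base by a different one (cyclic shift in ACGT order)."""
    idx = _CODE[np.ascontiguousarray(bases).view(np.uint8)]
    return _BASES[(idx + shifts) % 4]


def write_fastq(reads: list[str], path, quality: str = "I") -> None:
    """Write read sequences as FASTQ (gzip when the path ends in .gz)."""
    import gzip as _gzip

    if str(path).endswith(".gz"):
        fh_ctx = _gzip.open(path, "wt", compresslevel=4)
    else:
        fh_ctx = open(path, "w")
    with fh_ctx as fh:
        chunks = []
        for i, seq in enumerate(reads):
            chunks.append(f"@read{i}\n{seq}\n+\n{quality * len(seq)}\n")
            if len(chunks) >= 10000:
                fh.write("".join(chunks))
                chunks = []
        fh.write("".join(chunks))


def simulate_replicate_barcodes(
    truth: SimTruth,
    n_replicates: int = 9,
    antibodies: tuple[str, ...] = DEFAULT_REPLICATE_ANTIBODIES,
) -> tuple[Panel, pd.DataFrame, pd.DataFrame]:
    """Replicate-barcode concordance experiment.

    Emulates staining with a small pool where each selected antibody is
    independently conjugated to ``n_replicates`` distinct barcodes (the
    default 5 x 9 = 45-conjugate design). Per-cell molecule counts for the
    selected antibodies are drawn at the full sequencing depth shared over
    just those antibodies, then split multinomially (equal probability)
    across the replicate barcodes.

    Returns (expanded panel, original counts cells x antibodies, replicate
    counts cells x (antibodies x n_replicates)). Replicate column sums equal
    the original columns exactly.
    """
    config = truth.config
    missing = [a for a in antibodies if a not in truth.panel.names]
    if missing:
        raise KeyError(f"antibodies absent from panel: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    cells = truth.latent_time.index
    means = truth.mean_matrix.loc[cells, list(antibodies)].to_numpy()
    # renormalize: the replicate pool contains only these antibodies
    depth = config.mean_depth * np.exp(
        rng.normal(0.0, config.depth_sd, size=len(cells))
    )
    means = means / means.sum(axis=1, keepdims=True) * depth[:, None]
    r = config.nb_dispersion
    original = rng.negative_binomial(r, r / (r + means))

    rep_cols: dict[str, np.ndarray] = {}
    p = np.full(n_replicates, 1.0 / n_replicates)
    for j, ab in enumerate(antibodies):
        split = np.vstack([rng.multinomial(n, p) for n in original[:, j]])
        for k in range(n_replicates):
            rep_cols[f"{ab}_bc{k + 1}"] = split[:, k]

    barcodes = _random_barcodes(
        rng, len(antibodies) * n_replicates, AB_BARCODE_LEN, min_distance=3
    )
    tags = []
    by_name = truth.panel.by_name()
    for j, ab in enumerate(antibodies):
        src = by_name[ab]
        for k in range(n_replicates):
            tags.append(
                AntibodyTag(
                    antibody_name=f"{ab}_bc{k + 1}",
                    barcode=barcodes[j * n_replicates + k],
                    epitope_class=src.epitope_class,
                    pathway_group=src.pathway_group,
                    replicate_group=ab,
                )
            )
    panel = Panel(tags)
    original_df = pd.DataFrame(
        original.astype(np.int64), index=cells, columns=list(antibodies)
    )
    replicate_df = pd.DataFrame(
        {k: v.astype(np.int64) for k, v in rep_cols.items()}, index=cells
    )
    return panel, original_df, replicate_df
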