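"""End-to-end pipeline orchestration.

``run_pipeline`` glues the stages together in fixed order — (optionally)
simulate → demultiplex/count → background QC → filter → subsample → scale /
ratio → pseudotime → trends → K-S differential testing — writing every
artifact plus a provenance record into one run directory. Reruns with an
identical config and seed are identical for all outputs (stochastic stages
are seeded from the global seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .demux import assign_reads, count_umis, iter_fastq, merge_replicate_barcodes
from .difftest import results_frame, select_dynamic
from .io import write_count_matrix, write_json
from .panel import ReadLayout, load_panel, load_plate, save_panel, save_plate
from .pseudotime import (
    DEFAULT_DOWN_MARKER,
    DEFAULT_MARKERS,
    DEFAULT_UP_MARKER,
    compute_pseudotime,
    trend_all,
    trends_frame,
)
from .qc import (
    estimate_background,
    filter_cells,
    phospho_ratio,
    scale_minmax,
    subsample_counts,
)
from .simulate import SimConfig, default_layout, simulate_reads, simulate_truth, write_fastq

logger = logging.getLogger("scidseq")


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration.

    Stage blocks mirror the stage functions' keyword arguments; unknown keys
    anywhere are rejected before any work starts. Stage defaults equal the
    library defaults documented on each function.
    """

    outdir: str = "scidseq_run"
    seed: int = 0
    log_level: str = "INFO"
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)
    simulate: dict[str, Any] | None = None
    count: dict[str, Any] = dataclasses.field(default_factory=dict)
    qc: dict[str, Any] = dataclasses.field(default_factory=dict)
    normalize: dict[str, Any] = dataclasses.field(default_factory=dict)
    pseudotime: dict[str, Any] = dataclasses.field(default_factory=dict)
    difftest: dict[str, Any] = dataclasses.field(default_factory=dict)
    make_plots: bool = True

    _STAGE_KEYS = {
        "inputs": {"fastq", "panel", "plate", "layout"},
        "simulate": {f.name for f in dataclasses.fields(SimConfig)},
        "count": {"max_mismatch_ab", "max_mismatch_well", "umi_collapse"},
        "qc": {"min_total"},
        "normalize": {"depth"},
        "pseudotime": {"markers", "up_marker", "down_marker", "bin_size", "degree"},
        "difftest": {"alpha", "method"},
    }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        for block, allowed in cls._STAGE_KEYS.items():
            val = getattr(cfg, block)
            if val is None:
                continue
            extra = set(val) - allowed
            if extra:
                raise ConfigError(
                    f"unknown key(s) in {block!r} block: {sorted(extra)}"
                )
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig | dict) -> Path:
    """Execute all stages; returns the run directory.

    When the config has a ``simulate`` block, the inputs (FASTQ, panel sheet,
    plate layout, truth tables) are generated first; otherwise they are read
    from ``inputs``.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim = SimConfig(**sim_kwargs)
        logger.info("simulating truth: %d cell wells, %d antibodies",
                    sim.n_cell_wells, sim.panel_size)
        truth = simulate_truth(sim)
        layout = default_layout(sim.well_bc_len)
        reads, molecules = simulate_reads(truth, layout)
        fastq_path = outdir / "reads.fastq.gz"
        write_fastq(reads, fastq_path)
        save_panel(truth.panel, outdir / "panel.tsv")
        save_plate(truth.plate, outdir / "plate.tsv")
        (outdir / "layout.json").write_text(layout.to_json() + "\n")
        truth_dir = outdir / "truth"
        truth_dir.mkdir(exist_ok=True)
        truth.latent_time.to_csv(truth_dir / "latent_time.tsv", sep="\t")
        truth.true_counts.to_csv(truth_dir / "true_counts.tsv", sep="\t")
        molecules.to_csv(truth_dir / "molecules.tsv", sep="\t", index=False)
        panel, plate = truth.panel, truth.plate
    else:
        for key in ("fastq", "panel", "plate", "layout"):
            if key not in config.inputs:
                raise ConfigError(f"inputs.{key} required when not simulating")
            if not Path(config.inputs[key]).exists():
                raise ConfigError(f"inputs.{key}: {config.inputs[key]} does not exist")
        panel = load_panel(config.inputs["panel"])
        plate = load_plate(config.inputs["plate"])
        layout = ReadLayout.from_json(Path(config.inputs["layout"]).read_text())
        fastq_path = Path(config.inputs["fastq"])

    # --- demultiplex and count ---
    logger.info("demultiplexing %s", fastq_path)
    assigned, report = assign_reads(
        iter_fastq(fastq_path), layout, panel, plate,
        max_mismatch_ab=config.count.get("max_mismatch_ab", 1),
        max_mismatch_well=config.count.get("max_mismatch_well", 1),
    )
    raw = count_umis(assigned, panel, plate,
                     umi_collapse=config.count.get("umi_collapse", "exact"))
    write_count_matrix(raw, outdir / "counts_raw.tsv")
    write_json(report.to_dict(), outdir / "demux_report.json")

    # --- QC and normalization ---
    qc_report = estimate_background(raw)
    filtered = filter_cells(raw, config.qc.get("min_total", "auto"), report=qc_report)
    write_json(qc_report.to_dict(), outdir / "qc_report.json")
    logger.info("filter threshold %s: retained %s cells",
                qc_report.filter_threshold_used, qc_report.cells_retained)
    subsampled = subsample_counts(
        filtered, depth=config.normalize.get("depth", "min"), seed=config.seed
    )
    scaled = scale_minmax(subsampled)
    write_count_matrix(subsampled, outdir / "counts_subsampled.tsv")
    write_count_matrix(scaled, outdir / "counts_scaled.tsv")
    if panel.phospho_pairs():
        ratios = phospho_ratio(subsampled, panel)
        ratios.values.to_csv(outdir / "phospho_ratios.tsv", sep="\t")

    if panel.replicate_groups():
        corr, _ = merge_replicate_barcodes(scaled, panel)
        corr.to_csv(outdir / "replicate_correlations.tsv", sep="\t", index=False)

    # --- pseudotime and trends ---
    pt_cfg = config.pseudotime
    result = compute_pseudotime(
        scaled,
        markers=tuple(pt_cfg.get("markers", DEFAULT_MARKERS)),
        up_marker=pt_cfg.get("up_marker", DEFAULT_UP_MARKER),
        down_marker=pt_cfg.get("down_marker", DEFAULT_DOWN_MARKER),
        bin_size=int(pt_cfg.get("bin_size", 10)),
    )
    result.to_frame().to_csv(outdir / "pseudotime.tsv", sep="\t")
    write_json(
        {
            "markers": result.marker_names,
            "pc_variance_explained": list(result.pc_variance_explained),
            "orientation_flipped": result.orientation_flipped,
            "orientation_ambiguous": result.orientation_ambiguous,
        },
        outdir / "pseudotime_summary.json",
    )
    trends = trend_all(scaled, result, degree=int(pt_cfg.get("degree", 3)))
    trends_frame(trends).to_csv(outdir / "trends.tsv", sep="\t", index=False)

    # --- differential testing ---
    ks_results, concordance = select_dynamic(
        scaled,
        alpha=float(config.difftest.get("alpha", 0.001)),
        trends=trends,
        method=config.difftest.get("method", "asymp"),
    )
    results_frame(ks_results).to_csv(outdir / "ks_results.tsv", sep="\t", index=False)
    concordance.to_csv(outdir / "pathway_concordance.tsv", sep="\t", index=False)

    if config.make_plots:
        _plot_trends(scaled, result, trends, outdir / "plots")

    provenance = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "scidseq_version": __version__,
        "n_cells_analyzed": int(scaled.shape[0]),
        "n_antibodies": int(scaled.shape[1]),
    }
    write_json(provenance, outdir / "provenance.json")
    return outdir


def _plot_trends(scaled, result, trends, plotdir: Path) -> None:
    """One panel per pathway group: bin means with fitted cubic curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    plotdir.mkdir(parents=True, exist_ok=True)
    groups: dict[str, list[str]] = {"markers": list(result.marker_names)}
    for name in scaled.values.columns:
        pw = scaled.col_meta.loc[name].get("pathway_group")
        if pw is not None and not pd.isna(pw) and pw != "":
            groups.setdefault(pw, []).append(name)
    grid = np.linspace(0, 1, 100)
    for group, names in groups.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        for name in names:
            fit = trends[name]
            pts = ax.plot(fit.bin_centers, fit.bin_means, "o", ms=3, label=name)
            ax.plot(grid, fit.predict(grid), "-", color=pts[0].get_color())
        ax.set_xlabel("pseudo-time")
        ax.set_ylabel("scaled counts (10-cell bin mean)")
        ax.set_title(group)
        ax.legend(fontsize=6)
        fig.tight_layout()
        safe = group.replace("/", "-")
        fig.savefig(plotdir / f"trends_{safe}.png", dpi=100)
        plt.close(fig)
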