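# Methods

This note documents the models, defaults and numerical choices behind
`scidseq`, stage by stage, including what the synthetic-data generator does
and does not emulate.

## Read model and demultiplexing

A read is a single-end sequence carrying three non-overlapping segments in
0-based, half-open coordinates: a well barcode (configurable length, default
8 nt), a 10-nt antibody barcode, and a 15-nt UMI. The default layout is
contiguous in-line (`well | antibody | UMI`); because library architectures
vary (the well barcode may arrive on a PCR primer rather than in-line), the
layout is a free JSON-configurable parameter of both the parser and the
simulator rather than a fixed constant.

Barcode assignment is whitelist matching under a Hamming-distance tolerance.
Exact matches resolve by hash lookup; within tolerance *m*, the unique
nearest whitelist entry is returned, and **ties at the minimal qualifying
distance are rejected rather than guessed** — panels are designed with
discrete, well-separated barcodes, so an ambiguous observation signals an
error beyond the design tolerance. Unambiguous correction requires a
minimum pairwise barcode distance of `2m + 1`; this is enforced before
streaming begins (with `m = 1`, the default for both barcode kinds, a
precomputed single-substitution neighbour table makes correction O(1) per
read). UMIs are never error-corrected in the default `exact` collapse mode;
an optional `directional` mode additionally merges single-mismatch UMI
neighbours. Exact mode is the default because it is conservative and
directly checkable against a set-cardinality oracle. Base quality scores are
ignored by default.

Counting keeps one row per plate well — including empty wells, which are the
background measurement — and one column per panel antibody, regardless of
which combinations were observed. Per-read accounting (too short /
antibody-unassigned / well-unassigned / assigned) partitions the input
exactly; this invariant is asserted at run time.

## Background, filtering, normalization

Empty wells received no sorted cell, so their UMI totals estimate technical
background. The report uses **medians** (robust to outlier wells):
`background_fraction = median(empty totals) / median(cell totals)` and
`fold_separation` its reciprocal.

The default cell filter keeps cell wells whose total is at least 10× the
median empty-well total, with a floor of 500 UMIs. The published assay's
exact quality-control rule lives in supplementary material not reproduced
here, so this policy is a documented stand-in: the ~100-fold cell/empty
separation motivates a 10× guard band over background.

Depth normalization is **rarefaction**: each retained cell is subsampled
without replacement to a common depth (default: the minimum retained total,
which discards no cells). Sampling is multivariate hypergeometric per cell —
UMIs are discrete molecules, so without-replacement sampling is the correct
semantics (binomial thinning would allow an antibody to exceed its observed
count in expectation only, and would not conserve row totals exactly). Row
totals after subsampling equal the depth exactly, every entry is bounded by
its original count, and the operation is bit-reproducible under a seed.

Each antibody is then min-max scaled to [0, 1] across cells,
`(x − min)/(max − min)`, so abundant epitopes do not dominate downstream
analyses; zero-variance columns become all-zero with a warning. For each of
the 11 phospho epitopes with a measured total-protein partner, the per-cell
ratio `(phospho + 1)/(total + 1)` corrects activity for abundance (the
pseudocount of 1 guards against division by zero on sparse epitopes).

The pipeline order is fixed: filter → subsample → {scale | ratio}.

## Pseudo-time

Six anchor markers with established direction in epidermal differentiation
(ITGB1, ITGA6, TP63 fall; NICD, KLF4, TGM1 rise) define the ordering. PCA
runs on the cells × 6 scaled marker sub-matrix, **mean-centered but not
re-standardized to unit variance**: the 0–1 scaling already equalizes
epitope magnitudes, and a second standardization would double-correct. PCA
is computed with a full SVD (deterministic; no randomized solver).

PC1's sign is arbitrary, so orientation is fixed by a rule: the sign is
chosen so pseudo-time correlates positively with the up-marker (default
TGM1), with ties broken toward negative correlation with the down-marker
(default ITGB1); if both correlations are exactly zero the orientation is
kept and flagged ambiguous. The oriented score is min-max scaled to [0, 1].

Cells are ranked (stable sort, so ties and duplicated cells are handled
deterministically) and grouped into consecutive non-overlapping bins of 10
cells. A trailing remainder smaller than half a bin merges into the previous
bin; a larger remainder stays its own bin (220 cells divide evenly, so the
remainder policy only matters for other sizes). Each epitope's per-bin means
are fit with an unweighted ordinary-least-squares cubic over the bin centers
(mean pseudo-time of member cells); the fit is on bin means, not single
cells, because the binned profile is the object being summarized.
Coefficients are reported in ascending degree order; R² is clipped at 0 for
pathological fits, and a constant input yields coefficients `(c, 0, 0, 0)`.

## Differential testing

Every antibody's scaled per-cell values are compared between the two FACS
gates with the two-sample Kolmogorov–Smirnov test (`scipy.stats.ks_2samp`):
D is the supremum gap between empirical CDFs evaluated at the pooled points,
with two-sided p-values from the asymptotic Kolmogorov distribution using
the standard `sqrt(n_a·n_b/(n_a+n_b))` effective-n correction. At the group
sizes this assay produces (~163 vs ~57 cells) the asymptotic approximation
is well calibrated (measured null rejection rate 0.048 at α = 0.05 over
2,000 replicates); an exact method is available behind a flag for
`n_a·n_b ≤ 10,000`. Selection uses raw p < 0.001 with **no multiple-testing
correction on the primary path** — fidelity to the assay's selection rule —
while Benjamini–Hochberg q-values are reported as an informational column.
A pathway is flagged concordant when at least two of its significant
antibodies share a fitted trend direction (sign of the cubic at pseudo-time
1 minus 0). Tests run on scaled counts by default; whether to test scaled or
raw-subsampled values is an open choice, exposed as a flag.

## Synthetic-data generator

The generator emulates the study design end to end and is the
pipeline's ground-truth oracle. Defaults (one plate):

| parameter | default | meaning |
|---|---|---|
| `n_cell_wells` / `n_empty_wells` | 84 / 48 | sorted plate design (132 wells) |
| `panel_size` | 69 | antibody-DNA conjugates, incl. 6 anchor markers, 11 phospho/total pairs, 3 pathway groups |
| `mean_depth` | 5,000 | expected UMIs per cell; a realistic per-cell molecule yield for plate-based antibody counting |
| `background_fraction` | 0.01 | empty-well expected total relative to cells (the 1% / 100-fold regime) |
| `duplication_rate` | 2.0 | mean extra PCR copies per molecule (reads/molecule = 1 + Poisson(2)) |
| `error_rate` | 0.001 | per-base substitution probability |
| `nb_dispersion` | 10 | negative-binomial size; var = μ + μ²/10 (Poisson is the large-size limit) |
| `noise_sd` / `depth_sd` | 0.25 / 0.3 | lognormal per-cell-per-antibody noise and per-cell depth variation |
| `gate_cut` | 0.7 | latent-time threshold for the ITGB1+ / ITGB1low labels (≈ 163:57 at 220 cells) |
| `well_bc_len` | 8 | well barcode length (a free design parameter) |

Each cell draws a latent differentiation time t ~ U(0, 1). Marker
expectations follow logistic curves in their known directions with
**midpoints staggered across [0.25, 0.75]** (ITGA6 0.30, NICD 0.35, ITGB1
0.50, KLF4 0.55, TP63 0.70, TGM1 0.75) — distinct kinetics that keep every
stretch of the trajectory informative, so the latent ordering is actually
recoverable from the markers; pathway antibodies rise mildly (~3-fold);
other antibodies are static. Per-antibody baselines are lognormal across the
panel; each cell's expectations are rescaled to its depth, and counts are
negative-binomial. Empty wells draw Poisson counts at the background
fraction of the mean depth, distributed by the population-average
composition. Barcodes (well and antibody) are sampled with pairwise Hamming
distance ≥ 3, so single-mismatch correction is always unambiguous. Every
molecule gets a distinct random UMI within its (well, antibody) group;
reads are emitted with Poisson duplication, independent substitution errors
(an optional mode instead forces exactly k substitutions into every
antibody-barcode segment for error-correction stress tests), and a seeded
shuffle. The replicate-barcode experiment redraws the five selected
antibodies at full depth shared over only those antibodies — emulating a
dedicated 45-conjugate staining pool — and splits each count multinomially
over nine equal-probability barcodes.

All randomness flows from one integer seed (reads and the replicate
experiment use child seeds derived from it), so all outputs are
bit-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: base-quality profiles and adapter
read-through; indels (errors are substitutions only); ambient-antibody
composition differences between background and cells (empty wells share the
population-average composition); doublets; plate/batch effects; antibody
cross-reactivity or epitope-specific staining efficiency; and any deviation
of real count noise from the negative-binomial family. Recovery benchmarks
(e.g. pseudo-time vs latent time) certify the inference machinery under this
generative model, not the biological fidelity of the model itself.

## Problem sizes and determinism

The shipped tests and the acceptance script run at the design geometry:
84 + 48 wells × 69 antibodies at depth 5,000 for read-level checks
(~1.3 M reads), 220 cells for trajectory recovery, 2,000 replicates for K-S
calibration at 163/57, and 10,000 seeded draws for the rarefaction moment
check. Smaller geometries are used where the property under test does not
depend on scale. Stochastic assertions use moment-based bounds (typically
3 standard errors) rather than fixed magic numbers, except where a bound is
itself the property (e.g. replicate correlations > 0.9).

Known limitations: the directional UMI collapse is quadratic per
(well, antibody) group and intended for modest UMI sets; the demultiplexer
is a pure-Python stream (linear, ~200k reads/s) — adequate for plate-scale
data, not for droplet-scale libraries; and pseudo-time is a single linear
axis by construction, so branching trajectories are out of scope.
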