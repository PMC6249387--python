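# scidseq

Single-cell **Immuno-Detection by sequencing** (scID-seq) analysis: from
antibody-DNA-conjugate sequencing reads to a UMI-based single-cell protein
count matrix, and from that matrix to a pseudo-time ordering of epidermal
differentiation with per-epitope dynamics and differential statistics.

## The problem

In scID-seq, cells are immuno-stained in suspension with a panel of
antibodies, each covalently linked to a DNA tag carrying a 10-nt
antibody-identifying barcode. Single cells are FACS-sorted into the wells of
a 96-well-format plate (some wells deliberately left empty to measure
technical background), the tags are preamplified, a well-identifying barcode
is added, and everything is sequenced. Each read therefore contains three
segments: a **well barcode** (which sorted cell), a **10-nt antibody
barcode** (which epitope), and a **15-nt unique molecular identifier** (UMI;
which individual molecule, so PCR duplicates collapse to one count).

`scidseq` implements the full computational side of this assay:

| stage | what it does |
|---|---|
| `simulate` | ground-truthed synthetic experiments: plate design, latent differentiation trajectory, negative-binomial molecule counts, PCR-duplicated error-bearing reads |
| `demux` / `count` | segment extraction, error-tolerant barcode assignment (unambiguous single-mismatch correction), per-(well, antibody) distinct-UMI counting |
| `qc` | empty-well background estimation (median empty total / median cell total), cell filtering |
| `normalize` | sequencing-depth equalization by rarefaction (sampling without replacement, multivariate hypergeometric), per-antibody min-max scaling to [0, 1], phospho/total protein ratios |
| `pseudotime` | PCA on six anchor markers (ITGB1, ITGA6, TP63 down; NICD, KLF4, TGM1 up), oriented and scaled PC1 as pseudo-time, 10-cell bin smoothing, third-order polynomial trend fits |
| `difftest` | two-sample Kolmogorov–Smirnov test of every epitope between the ITGB1+ and ITGB1low sorted gates (significance at p < 0.001), pathway concordance |

The pseudo-time statistic is the first principal component of the
mean-centered, 0–1-scaled marker sub-matrix: for cell $i$ with scaled marker
vector $x_i$,

$$\tau_i = \frac{s_i - \min_j s_j}{\max_j s_j - \min_j s_j}, \qquad
s_i = \sigma \, w_1^\top (x_i - \bar x),$$

where $w_1$ is the leading eigenvector of the marker covariance matrix and
the sign $\sigma \in \{+1, -1\}$ is fixed so that $\tau$ correlates
positively with the designated up-marker (TGM1). Epitope dynamics are
summarized by the mean of each consecutive 10-cell bin along $\tau$ and an
ordinary-least-squares cubic $\hat y(\tau) = c_0 + c_1\tau + c_2\tau^2 +
c_3\tau^3$. Differential epitopes are selected with the two-sample K-S
statistic $D = \sup_x |\hat F_a(x) - \hat F_b(x)|$.

## Worked example

```python
from scidseq import *
from scipy.stats import spearmanr

truth = simulate_truth(SimConfig(seed=7))          # 84 cells + 48 empty, 69 antibodies
reads, molecules = simulate_reads(truth)
print(f"simulated {len(reads):,} reads covering {len(molecules):,} molecules")

assigned, report = assign_reads(reads, default_layout(), truth.panel, truth.plate)
print(f"assigned {report.n_assigned:,}/{report.n_reads_total:,} reads "
      f"({report.n_ab_corrected:,} barcode-corrected)")

raw = count_umis(assigned, truth.panel, truth.plate)
qc = estimate_background(raw)
print(f"cell/empty fold separation: {qc.fold_separation:.1f} "
      f"(background {100 * qc.background_fraction:.2f}%)")

scaled = scale_minmax(subsample_counts(filter_cells(raw, "auto"), "min", seed=7))
result = compute_pseudotime(scaled)
rho = abs(spearmanr(result.pseudotime,
                    truth.latent_time.loc[result.pseudotime.index])[0])
print(f"PC1 explains {result.pc_variance_explained[0]:.0%} of marker variance; "
      f"Spearman |rho| vs latent time = {rho:.2f}")

fits = trend_all(scaled, result)
ks, concordance = select_dynamic(scaled, alpha=0.001, trends=fits)
print(f"{sum(r.significant for r in ks)}/{len(ks)} epitopes differ "
      f"between gates (K-S p < 0.001)")
```

Output:

```
simulated 1,323,780 reads covering 441,266 molecules
assigned 1,323,690/1,323,780 reads (12,928 barcode-corrected)
cell/empty fold separation: 101.0 (background 0.99%)
PC1 explains 52% of marker variance; Spearman |rho| vs latent time = 0.90
13/69 epitopes differ between gates (K-S p < 0.001)
```

Reading the numbers: wells that received a sorted cell carry ~100-fold more
UMIs than empty wells, i.e. about 1% of the signal is technical background;
the oriented, scaled PC1 of the six anchor markers explains roughly half of
the marker variance and tracks the simulator's hidden differentiation time
(rank correlation 0.90); and the K-S screen at p < 0.001 flags the epitopes
whose distributions separate the ITGB1+ (self-renewing) and ITGB1low
(differentiating) gates.

The same workflow is available from the shell:

```bash
scidseq run --outdir run1 --seed 7          # simulate + analyze end-to-end
scidseq count --fastq reads.fastq.gz --panel panel.tsv --plate plate.tsv \
              --layout layout.json --out counts.tsv --report demux.json
scidseq normalize --counts counts.tsv --depth min --seed 7 --out scaled.tsv
scidseq pseudotime --counts scaled.tsv --out pt.tsv --trends-out trends.tsv
scidseq difftest --counts scaled.tsv --alpha 0.001 --out ks.tsv
```

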