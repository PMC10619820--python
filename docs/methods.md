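# Methods

## Model and procedure

`binpbs` treats the genome as an ordered set of fixed-width windows (bins)
and models per-bin read counts, after local corrections, as a two-component
mixture: a fraction λ of bins are *background* — windows without the ChIP
target, whose rescaled counts follow a gamma distribution with shape α and
rate β — and the remainder carry signal at systematically higher counts.
Nothing is assumed about the signal component; the method only asks, at each
count value `x`, how much of the observed density is unexplained by the
fitted background. The pipeline stages run in a fixed order:

1. **Binning.** Each chromosome is tiled with non-overlapping `bin_size`
   windows starting at 0; the trailing partial window is emitted but flagged
   excluded, so bin indices remain reconstructible from coordinates. Reads
   with MAPQ below `mapq_min`, and unmapped / secondary / supplementary /
   duplicate-flagged reads, are ignored. A kept read contributes
   `overlap_bp / read_length` to every bin it overlaps, so boundary reads
   split their unit weight instead of double-counting or vanishing; total
   counted weight equals the number of kept reads. Bins overlapping a
   blacklist interval by ≥ 1 bp are excluded.
2. **Mappability rescaling.** Each bin's mappability is the mean, over its
   span, of the fraction of positions where a read of the experiment's
   length aligns uniquely (published tracks exist for 25/36/50/75/100 bp;
   paired-end data use the 100 bp track since mate pairs have no single
   length). Bins scoring below `min_mappability` (default 0.5) are excluded;
   remaining counts are divided by the score, which can only increase them.
3. **CNV detection and ploidy rescaling.** On the matched *input control*
   (so enrichment is never mistaken for copy number), usable bins in genome
   order are split into `n_subsets` (default 20) contiguous equal-count
   subsets that deliberately ignore chromosome boundaries; each subset's
   count distribution gets a Hartigan–Hartigan dip test, and a CNV is called
   when any Bonferroni-adjusted p-value (α/n_subsets) is significant. Only
   then does the costlier ploidy estimation run: counts are smoothed with a
   running median (window 11 bins), segmented at jumps exceeding 3
   scaled-MADs of the smoothed differences, and a gaussian mixture
   (1–6 components, BIC-selected with a margin of 10, length-weighted) is
   fitted to segment medians. The component holding the most bins is labeled
   diploid; each bin's ratio is its component mean over the diploid mean,
   with components within 10% of diploid snapped to 1 (copy states are
   discrete — 0.5, 1.5, 2 × — so near-diploid components are sampling
   noise). Epitope-track counts are divided by the per-bin ratio.
4. **Background fit.** θ is the `theta_quantile` sample quantile of the
   rescaled counts (default the median; raise or lower it when more or less
   of the genome is expected to carry signal). (α, β, λ) minimize the
   modified Cramér–von Mises distance ω² between the empirical CDF and the
   λ-scaled gamma CDF over count values ≤ θ.
5. **PBS.** Each bin's count is mapped to a histogram cell and scored
   `PBS = (f − λf*)/f` where `f > λf*`, else 0, clamped to [0, 1].
6. **Fit quality.** `q` integrates the excess of λf* over f above θ — the
   mirror image of PBS, measuring where the background *overshoots* data the
   optimizer never saw. q < 0.05 is a good fit.

## Estimators and numerical choices

**Empirical distribution.** A fixed-width histogram with `n_grid` (default
1000) cells spanning [0, 99.9th percentile] plus one overflow cell to the
maximum; the density normalizes to 1 and the CDF is evaluated at cell
midpoints. A histogram rather than a kernel estimator keeps PBS
piecewise-constant — identical counts always receive identical PBS — and
exactly reproducible.

**ω² quadrature.** Midpoint rule over grid cells with midpoint ≤ θ,
weighting the squared CDF residual by the gamma density times the cell
width. ω² ≥ 0 always, and → 0 as a pure-gamma sample grows with λ = 1.

**Optimization.** Nelder–Mead on transformed parameters (log α, log β,
logit λ, so λ is constrained to (0, 1]) from a method-of-moments start on
the sub-θ counts, with three fixed perturbed restarts; the best objective
wins and a convergence flag is reported. The transforms make the search
unconstrained; λ̂ of a pure-background sample sits at the boundary
(≈ 0.999+).

**Density smoothing for the PBS ratio.** The raw per-cell density ratio is
noisy: with ~200–1500 bins per cell, a few percent of pure-background bins
would clear PBS > 0.1 on sampling noise alone, contradicting the expected
input-control behavior (background encompassing the whole distribution).
`compute_pbs` therefore applies a centered moving average over
`density_smooth` cells (default 9, ~1% of the count range) to the density
entering the ratio — the posterior the ratio estimates varies slowly on
that scale, so the bias is negligible while the false-signal fraction on a
λ = 1 genome drops from ~1–5% to ~0.2% and per-decile calibration against
the true posterior improves roughly twofold. `density_smooth=1` restores
the raw histogram ratio. The ω² fit is CDF-based and unaffected.

**q and grid resolution.** On *sampled* data the q of a well-specified fit
is dominated by one-sided histogram noise and therefore grows with grid
resolution (≈ √n_grid); it stays far below 0.05 at the default settings and
realistic genome sizes. The quadrature itself is grid-stable: on noise-free
constructed densities q matches the closed-form overshoot area across
n_grid ∈ [500, 4000]. q also includes the analytic tail term
λ(1 − F*(x_max)): beyond the largest observed count the empirical density
is zero, so any remaining fitted background mass is pure overshoot — without
this term a background fitted to a sharply truncated count distribution
(the canonical failure mode) would incorrectly score q ≈ 0. Note q is
one-sided by design: data exceeding the background is the *signal*
direction and is PBS's job, not q's.

**Dip statistic.** Implemented from the sorted-sample greatest-convex-
minorant / least-concave-majorant algorithm (accelerated with numba when
available, pure Python otherwise) and verified in the test suite against an
independent brute-force oracle: minimax fitting of a piecewise-linear
unimodal CDF by linear programming, enumerating the candidate mode segment.
P-values are calibrated by simulation against uniform(0, 1) samples of the
same size (the standard, conservative null for unimodality testing), with
an add-one correction — so the smallest attainable p is 1/(n_boot + 1), and
`n_boot` (default 1000) must exceed n_subsets/α for a Bonferroni-corrected
detection to be possible at all. Within one detection run the null is
simulated once per distinct subset size and shared.

**Thresholds.** All PBS thresholds are strict (`> cutoff`), matching the
convention "PBS > 0.9"; category intervals are half-open `[e, e')` with the
last closed at 1. Fisher's exact test (two-sided, cross-product odds ratio)
handles 2×2 stratified comparisons.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `bin_size` | 5000 bp | window width; below ~3 kB counts become discrete and the continuous gamma model needs adaptation (a warning is issued) |
| `mapq_min` | 1 | exclude multi-mapped reads |
| `min_mappability` | 0.5 | exclusion cutoff; scores in [0.5, 1) divide counts |
| `theta_quantile` | 0.5 | background-dominated fraction for fitting |
| `n_subsets` | 20 | CNV dip-test subsets |
| `n_grid` | 1000 | histogram cells |
| `density_smooth` | 9 cells | moving-average window for the PBS ratio |
| `pbs_threshold` | 0.9 | annotation export cutoff |
| good-fit bound | q < 0.05 | fit-quality classification |

## Synthetic data

The generator draws each bin independently from
`λ · Gamma(α, β) + (1 − λ) · Gamma(α·k, β)` — the signal family defaults to
a gamma with the same rate and shape multiplied by the enrichment factor k,
so its mean is k× the background mean, its relative spread shrinks with k,
and k = 1 is exactly the background. Defaults (α = 3, β = 0.1, λ = 0.8,
k = 6) emulate a well-sequenced 5 kB-binned ChIP experiment with a mean
background of 30 reads per bin; CNV simulations use α = 100, β = 1 (mean
100, CV 10%), realistic for a deep input control. Signal layout is either
random bins (punctate, narrow-mark-like) or contiguous blocks (broad-mark-
like); CNV segments multiply counts by their copy ratio and low-mappability
bins by their score, emulating the distortions the rescaling stages undo.
The generator returns truth labels and the closed-form posterior
`P(signal | x) = 1 − λ f_b(x) / f_mix(x)`, the oracle for PBS calibration.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: spatial autocorrelation of counts (each bin
is independent), GC- and chromatin-state-dependent background dispersion,
fragment-level read structure, unannotated assembly artifacts, and signal
that departs from a single parametric family. Calibration results on
simulations are a correctness check of the estimator, not a guarantee of
biological calibration.

## Problem sizes in tests

Unit tests run on 10–100k-bin genomes; the behavioral suite uses 500k bins
for fit-quality and input-control checks (a human genome at 5 kB is ~619k
bins), 200k bins for parameter-recovery (20 replicates), calibration, and
phenomenology checks, and a 100k-bin genome with a 10%-of-genome 1.5×
segment for the CNV round trip, with 20 diploid 20k-bin replicates for the
false-positive check.

## Known limitations

- The 20-subset dip scan is powered for CNVs large enough to shift a
  meaningful fraction of a subset's bins (subsets are ~n_bins/20); an
  isolated event of a few tens of kB cannot produce subset-level
  multimodality and will be missed. The segment must also not align exactly
  with subset boundaries — detection comes from subsets containing both
  copy states.
- Dip-based detection needs the two copy states' count modes separated
  relative to the background dispersion; it is effective for deep input
  controls (CV ≲ 20%), not for shallow ones.
- PBS is undefined (missing) for bins whose count falls in an empty
  histogram cell; counts beyond the fitted grid take the overflow cell's
  PBS (≈ 1) and their number is recorded in the track metadata.
- The raw PBS-vs-count profile can be non-monotone in sparse tails; an
  isotonic-regression option exists (off by default, flagged in metadata).
- λ placement in the q integrand follows the prose definition (scaled
  background λf* exceeding f), consistent with PBS defining signal as
  f exceeding λf*.
- No GC correction, no allele-specific or subclonal copy-number modeling,
  no fragment reconstruction for paired-end data (each mapped mate counts
  as a read).
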