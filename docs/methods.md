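# Methods

This note documents the models and procedures scnkit implements, the
parameter defaults and why they were chosen, what the synthetic generators
do and do not emulate, and the numerical decisions that affect results.

## Single-cell QC and normalisation

Cells are retained when they have at least 200 and fewer than 10,000 total
UMIs, less than 10% of UMIs from mitochondrial genes (matched
case-insensitively on the `mt-` prefix unless an explicit list is given)
and at least 100 detected genes; genes are retained when detected in at
least three cells. Cells surviving the hard thresholds are additionally
screened as potential multiplets: any cell beyond three scaled median
absolute deviations (MAD × 1.4826, two-sided) from the median on total
UMIs, detected genes or mitochondrial percentage is removed, with the
median/MAD computed on the post-threshold cells.

Each pass applies the filters in the fixed order gene → cell thresholds →
MAD, and passes repeat until no further cell or gene is removed. The
fixpoint guarantees idempotency — removing cells can push a gene below the
three-cell rule, and removing outliers shifts the MAD — at the cost of
occasionally removing slightly more cells than a single pass would. A MAD
of zero makes the outlier rule inert, so degenerate data (identical cells)
are not emptied. The mitochondrial percentage of a zero-total cell is
defined as 0; such cells are removed by the total-UMI floor regardless.

Normalisation is `ln(1 + count × 10,000 / cell_total)`. The +1 pseudocount
keeps zeros at zero (and the matrix sparse); per cell,
`Σ_genes (e^value − 1) = 10,000` exactly for cells with nonzero totals.
Zero-total cells are an error: they must be filtered first.

## Clustering and condition purity

Cells are embedded on the top principal components (default 50) of the
log-normalised matrix and clustered either by k-means (exact k, seeded) or
by Leiden community detection on a symmetrised 15-nearest-neighbour graph.
For the graph method a requested k is reached by bisection on the
resolution parameter; k = 1 short-circuits to a single community. Labels
are relabelled 0..k−1 by decreasing cluster size, which together with the
fixed seeds makes assignments reproducible. These are plumbing defaults —
no claim is made that they reproduce any particular commercial pipeline's
cluster boundaries.

Condition purity ("coverage") of a cluster is the percentage of its cells
carrying the majority condition label, e.g. 494 night cells in a cluster of
500 give 98.8%.

## Negative-binomial exact test

Counts are modelled per gene as NB(mean μ, dispersion φ) with
`var = μ + φμ²`. The test of group A vs group B:

1. **Size factors** default to cell total / median cell total over the
   tested cells and are rescaled to median 1, making p-values invariant to
   their overall scale.
2. **Dispersion** is estimated per gene by method of moments on size-factor
   normalised counts and shrunk toward the across-gene mean ξ,
   `φ* = δξ + (1−δ)φ̂`. The weight minimises estimated mean squared error:
   `δ = v̄ / (v̄ + τ̂²)`, where `v̄` is the mean delta-method sampling
   variance of the moment estimator — `Var(φ̂) ≈ σ⁴(κ_excess + 2)/(n μ⁴)`
   with the NB fourth moment evaluated at the target dispersion — and `τ̂²`
   is the across-gene scatter of φ̂ around ξ in excess of `v̄`. δ grows
   toward 1 when the scatter is mostly sampling noise (shrink hard) and
   toward 0 when genes genuinely differ in dispersion (shrink little).
3. **Exact p-value**: normalised counts are rounded to integers and the
   test conditions on the total T across both groups. A sum of n iid
   NB(μ, φ) variables is NB with size n/φ, so the group totals are
   NB(n_A μ, n_A/φ) and NB(n_B μ, n_B/φ) with μ estimated as T/(n_A+n_B);
   the two-sided p-value sums the probabilities of all splits (k, T−k) with
   joint probability not exceeding the observed split's, normalised over
   all splits. φ → 0 falls back to the Poisson limit. Reported group means
   are the unrounded normalised means.
4. **Multiplicity**: Benjamini–Hochberg across genes;
   `log2fc = log2((mean_A + 1)/(mean_B + 1))` (positive = up in A), the
   unit pseudo-mean avoiding division by zero. Genes with zero counts in
   both groups get p = 1 and log2fc = 0.

The implementation is verified against a brute-force oracle that
enumerates every per-cell count vector compatible with the conditioned
total on tiny instances, and calibrated on planted null data (type-I error
at α = 0.05 within [0.03, 0.07] over 2,000 genes).

Per-cluster markers are one-vs-rest tests, ranked by log2 fold change among
genes with adjusted p < 0.05, ties broken by adjusted p then gene name.

## Ligand–receptor topology

Edge weights use **raw** count means ("average cellular count"), not
log-normalised values: `W[i, j] = mean_L(i) × mean_R(j)`, including the
diagonal (autocrine) entries, which are retained and exportable separately.
W is a rank-one outer product by construction; the interesting structure
enters through which clusters express ligand vs receptor and how that
changes between day and night.

Scaling to [0, 1] is min–max over the union of the day and night matrices
of the same axis (default `axis_joint_minmax`), so that σ = Σ W_scaled is
comparable across conditions — a per-matrix mode exists for single-figure
style maps. How the original "scaled to its respective overall expression
range" should be operationalised is genuinely open; joint scaling is the
only choice under which a day/night σ ratio is meaningful, which is why it
is the default. A constant matrix scales to zero with a warning. An axis
whose receptor (or ligand) has no detected counts yields a zero network,
not an error.

Source ("distributor") clusters are flagged when their mean ligand count
exceeds twice the grand mean **and** the ligand is a significant one-vs-rest
marker of that cluster (exact test, BH across the k cluster tests,
adjusted p < 0.05, up-regulated direction only). Day/night comparison
reports edge-wise differences on jointly scaled weights, the σ ratio
(defined 0 for an empty night network), and a "disassembled" flag when
σ_night < 0.25 σ_day.

Positivity calls for co-expression (Venn) summaries default to nonzero raw
count; the high-expresser rule — normalised expression above 90% of the
overall expression range — is available for visualisation-style sets.
Directional overlap percentages and each set's share of the pairwise union
are reported; empty sets yield 0 with a warning.

## Rhythm analysis

**Model.** `y(t) = c + A·exp(−λt)·cos(2π(t−φ)/τ)`, fitted by trust-region
nonlinear least squares with bounds A ≥ 0, λ ∈ [0, 2]/h, τ inside the
period window (default 18–40 h). Initial values come from the dominant
discrete-Fourier component inside the window (amplitude 2|Y|/n, phase from
the component angle); if no in-window spectral peak exists the fit is
reported failed with RAE = ∞ and is never classified rhythmic. φ is
reported as the time of the cosine reference peak reduced mod τ into
[0, τ). BioDare's FFT-NLLS fits multiple components; a single damped
component is sufficient for the recovery properties validated here and the
extension point is the model class.

**Uncertainty.** The parameter covariance is `s²(JᵀJ)⁻¹` with
`s² = SSR/(n−5)`. RAE is the half-width of the ~95% confidence interval of
the amplitude divided by the estimate, `1.96·SE(Â)/Â`; the original
analysis suite's internal definition is not published, so this is a
declared substitute calibrated by the same acceptance property it serves
(noise-only false-positive rate ≤ 5%). GOF is `1 − SSR/SST`.

**Classification.** "Initiated" requires τ ∈ [23.5, 34.5] h (inclusive
bounds) and RAE < 0.3 (strict).

**Detrending.** Centered moving averages with edge truncation: baseline
window 24 h (one nominal circadian cycle; only "detrended" is specified
upstream, so the window is a package default), smoothing window 2.5 h.
Windows are rounded to an odd sample count. Detrending attenuates the
oscillation by the known Dirichlet-kernel gain of the two windows (tested
against the closed form); period-recovery tests therefore fit raw traces,
and phase maps, which must tolerate trends, absorb the common attenuation.

**Peaks.** Local maxima with prominence ≥ 0.2 of the signal range and
≥ 16 h separation; the trace is padded below its minimum so boundary peaks
are detected, and interior peak times are refined by a least-squares
parabola over ±3 h, which suppresses the sampling-grid quantisation (30-min
default) and residual noise.

**Phase shifts.** Pre-treatment peaks (≥ 3) define period and phase by a
linear fit of peak time on cycle index; the shift is the mean deviation of
the first three post-treatment peaks from the extrapolated continuation,
positive = delay. Peaks within half a baseline window (12 h) of the trace
ends or of the treatment time are discarded: there the moving average mixes
pre- and post-treatment regimes (or truncates), and the resulting extrema
are filter artifacts. With this exclusion an amplitude-only change produces
zero shift (amplitude/phase orthogonality) and noiseless recovery is exact.

**Waveform changes.** Cycles are delimited by troughs of the detrended
trace; the first full post-treatment cycle (anchored at the first
post-treatment trough — a reproducible anchor) is compared with the last
full pre-treatment cycle. Baseline is the cycle mean of the raw signal,
amplitude (max−min)/2 of the raw signal within the cycle, both reported as
relative changes; the period change comes from separate damped-cosine fits
of the pre and post segments.

**Circular statistics.** Phases map to angles θ = 2π·phase/τ. The Rayleigh
mean resultant length is R = |Σe^{iθ}|/n and the p-value uses the standard
finite-n approximation `p = exp(√(1+4n+4(n²−Rn²)) − (1+2n))` (Zar), checked
against an independent circular-statistics implementation. Phase maps
exclude ROIs whose mean raw signal falls below a user-supplied threshold
(the appropriate value is preparation-specific, hence required, default 0
in the pipeline config); relative phases are expressed against the
circular mean of the initiated ROIs and R is computed over initiated
phases. PRC bins are anchored at CT0 ([0,3), [3,6), …) with CT reduced
mod 24, so CT 23.9 and CT 0.5 fall in different bins. CT registration
between reporters is `CT(x) = (CT_ref + (φ_x − φ_ref)) mod τ`, warning when
the two periods differ by more than 1 h.

## Synthetic data

**Counts.** UMIs are NB(mean, size) with `var = μ + μ²/size`; the size
parameter is shared across genes by default (2, a typical UMI
overdispersion, and the shrinkage target of sSeq-style estimators).
Cluster-specific ligand/receptor programs multiply the ligand mean in
source clusters and the receptor mean in target clusters; circadian genes
are multiplied by their fold in cells of the day condition (the first
condition listed, configurable). Planted low-quality cells: low-UMI cells
(means scaled to ~100 total, below the 200 floor), high-mito cells
(multinomial draw of 2,000 UMIs with a 12% mitochondrial share) and
doublets (sums of two random good cells, the standard convention). Cell
conditions are allocated by largest remainder and shuffled, so fractions
are exact up to rounding.

**Traces.** Damped cosine plus baseline offset, linear and/or exponential
trend (PMT baseline drift is roughly monotone) and iid Gaussian noise,
sampled every 30 min by default (the time resolution of long-term live
imaging). Config invariants require ≥ 2 periods of data and ≥ 8 samples
per period so that fits are identifiable. ROI grids plant exactly
`round(fraction × n)` rhythmic ROIs at random positions, with phase linear
in the column index; non-rhythmic ROIs carry trend + noise only. Per-ROI
seeds are spawned from the base seed, so grids are reproducible and ROIs
independent.

**What is not emulated:** ambient RNA, batch effects, empty droplets,
spatial structure within the SCN, non-Gaussian photon statistics,
cross-ROI bleed or coupling between oscillators. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not robustness to every artifact of real preparations.

**Problem sizes.** Validation runs use 2,000 null genes at 200 vs 200
cells for test calibration, 600-cell day/night mixtures for clustering
purity, 100–200 fit replicates for period/RAE properties and 10×10 ROI
grids for phase maps — sizes at which the Monte-Carlo error of each
property is comfortably below its assertion tolerance.

## Known limitations

- The exact test rounds normalised counts to integers; with extreme size
  factor spread this discretisation can distort small-count genes.
- Single-component FFT-NLLS under-fits traces with strong harmonics or
  period drift; the damping term absorbs slow amplitude trends only.
- Leiden resolution bisection may not reach exactly k communities on
  pathological graphs (it warns and returns the nearest partition).
- The σ day/night comparison assumes a cluster correspondence across
  conditions; when cluster sets differ a user-supplied mapping is required.
- Phase-map Rayleigh statistics are computed over initiated ROIs only;
  slices with < 2 initiated ROIs yield NaN coherence.
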