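# scnkit

Analysis toolkit for the suprachiasmatic nucleus (SCN), the hypothalamic
master circadian pacemaker: it quantifies how neuropeptide signalling axes
(Prok2–ProkR2, VIP–VPAC2, AVP–AVPR1A, GRP–GRPR) wire the SCN's neuronal
sub-populations together, and how well individual cells and tissue regions
keep circadian time.

The package covers two complementary pipelines plus a synthetic-data
generator that makes every stage testable without sequencing or imaging
data:

1. **Transcriptomic topology** (droplet scRNA-seq UMI counts)
   - cell/gene QC: cells with ≥ 200 and < 10,000 total UMIs, < 10%
     mitochondrial content and ≥ 100 detected genes; genes detected in ≥ 3
     cells; residual multiplets removed beyond 3 scaled median absolute
     deviations on any metric
   - normalisation to 10,000 UMIs per cell, natural-log transformed
   - k-means or Leiden graph clustering on PCA of log-normalised counts,
     with per-cluster condition purity ("cluster coverage")
   - a negative-binomial **exact test** for day/night differential
     expression of UMI counts: size-factor normalisation, method-of-moments
     dispersion with sSeq-style shrinkage, conditional enumeration of group
     splits, Benjamini–Hochberg correction
   - ligand–receptor network inference between clusters: the strength of
     signalling from cluster *i* to cluster *j* for an axis (L, R) is
     `W[i, j] = mean_count(L | cluster i) × mean_count(R | cluster j)`,
     min–max scaled jointly over day and night, with overall axis
     connectivity `σ = Σᵢⱼ W[i, j]`, ligand-enriched source-cluster flags
     and day-vs-night comparison
2. **Circadian rhythm analysis** (bioluminescence / fluorescence traces)
   - detrending (24-h moving-average baseline) and 2.5-h moving-average
     smoothing
   - FFT-initialised nonlinear least-squares fit (FFT-NLLS) of a damped
     cosine `y = c + A·exp(−λt)·cos(2π(t−φ)/τ)`, reporting the relative
     amplitude error RAE (95% CI half-width of Â over Â) and goodness of
     fit
   - rhythmicity ("initiated") classification: τ ∈ [23.5, 34.5] h and
     RAE < 0.3
   - Rayleigh phase-coherence statistics, ROI-grid phase maps, peak
     detection, treatment phase shifts (positive = delay), waveform
     (baseline/amplitude/period) changes, phase-response-curve binning and
     CT registration between reporters

## Worked example

```python
from scnkit import RhythmConfig, generate_biolum_trace, fit_rhythm

cfg = RhythmConfig(period_h=24.6, phase_h=8.0, amplitude=1.0, damping_per_h=0.008,
                   noise_sd=0.1, duration_h=144.0, sampling_interval_h=0.5, seed=4)
print(fit_rhythm(generate_biolum_trace(cfg)).summary())
```

```
Damped-cosine rhythm fit: trace
==============================================
parameter                 estimate     std err
----------------------------------------------
period tau (h)             24.6198      0.0334
phase phi (h)               7.9620
amplitude A                 1.0022      0.0221
damping lambda (/h)         0.0077
baseline c                  0.0084
----------------------------------------------
RAE: 0.0433   GOF (1-SSR/SST): 0.9524   n = 289
initiated: True (period in [23.5, 34.5] h and RAE < 0.3)
```

The fit recovers the generating parameters (τ = 24.6 h, A = 1, λ = 0.008/h)
within one standard error; the low RAE marks the trace as robustly
rhythmic. On the topology side:

```python
from scnkit import edge_weights, network_sigma

W = edge_weights([2, 0, 1], [0.5, 1, 0])   # cluster means of ligand, receptor
# W = [[1.0, 2.0, 0.0], [0.0, 0.0, 0.0], [0.5, 1.0, 0.0]];  sigma = 4.5
```

Cluster 0 (ligand mean 2) broadcasts most strongly to cluster 1 (receptor
mean 1); a cluster without ligand expression (row 1) sends nothing.

A full synthetic run — simulation, QC, clustering, differential
expression, per-axis day/night networks and an ROI phase map, each with a
JSON run manifest — is one command:

```sh
scnkit run all --config config.yaml --seed 1
```

and the rhythm tools are available standalone (`scnkit rhythm fit|phasemap|shift|prc`).

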