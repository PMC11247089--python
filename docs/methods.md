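# Methods note

This note defines the models and conventions implemented in `circaclock`,
states what the synthetic generator does and does not emulate, and records
the numerical choices that affect results. It makes no empirical claims
beyond what the test suite and `scripts/acceptance.py` compute.

## Harmonic regression model

Per-gene expression (log2 units) is modelled against time `t` (hours) as

```
X(t) = a·sin(2πt/24) + b·cos(2πt/24) + d·sin(2πt/12) + e·cos(2πt/12) + f
```

fitted by ordinary least squares. Derived quantities:

- **R² (rhythmicity)** — coefficient of determination of the fit; the
  rhythm-strength readout throughout the package.
- **peak / trough phase** — argmax/argmin of the fitted curve on a 0.01 h
  grid over [0, 24). A grid is used (rather than a closed form) because the
  two-harmonic curve's extrema have no simple closed form; 0.01 h is far
  below every tolerance used anywhere in the package.
- **amplitude** — half the fitted peak-to-trough range; **mesor** — the
  intercept `f`.
- Fits need ≥ 6 samples (5 parameters + 1). Constant input is flagged
  `degenerate` with R² = 0.

## Δφ–r_S relationship and the CCM

For noiseless sinusoids sampled evenly over one cycle, the Spearman
correlation of a gene pair is +1 at phase difference Δφ = 0 h, −1 at 12 h,
and ≈ 0 at ±6 h; the curve is even in Δφ and monotone on [0, 12] h.
`dphi_rs_curve` computes it exactly; the sinusoids are rounded to 12
decimals first so values that are mathematically equal (e.g. mirror-image
samples of an anti-phase pair) are exact rank ties in float arithmetic —
without this, r_S(12 h) lands at −0.998 instead of −1.

The circadian correlation matrix (CCM) is the symmetric matrix of pairwise
Spearman correlations over a gene list; genes absent from a dataset appear
as missing rows/columns. Cosine similarity S_c between two CCMs is the
normalized inner product of the flattened strict upper triangles (diagonal
excluded — self-correlations carry no information), restricted to genes
non-missing in both.

## Phase-group selection

Given a reference gene (default PER3) and a second reference in anti-phase
(default ARNTL): the top-`k` genes by r_S to the reference form the
in-phase group, the bottom-`k` the anti-phase group; the quadrature group
contains genes with −0.4 < r_S < 0.4 to *both* references whose harmonic
fit has R² > 0.8 (so weak correlation reflects a ±6 h offset, not
arrhythmicity). Ranking ties are broken by gene name for determinism.
Defaults: k_top = k_bottom = 100, band (−0.4, 0.4), R² > 0.8.

## Snapshot phase assignment

**PCA phase.** List genes are z-scored across samples; samples are
projected on the first two principal components and assigned
φ = atan2(PC2, PC1)·24/2π mod 24. Without z-scoring, high-mesor genes
dominate the components and the circle degenerates. Sample order is
shuffled (seeded) before the decomposition purely to document that the
result is order-invariant. Assignments whose first two components explain
< 0.5 of the variance are flagged *weak* (threshold calibrated on null
simulations to < 5 % false-pass).

**Orientation.** The PCA circle leaves a reflection and a rotation free.
Two modes resolve them: *supervised* (validation only) minimizes the median
absolute circular error against recorded times over both reflections and a
0.05 h offset grid; *anchored* (snapshot-usable) sets the offset so the
reference gene's harmonic fit against φ peaks at a configurable anchor hour
(default 12.0) and picks the reflection for which the quadrature gene
(RORC role) peaks *after* the reference — the conserved +6 h geometry.

**Proxy time.** φ = quadrant-aware angle of (z_PER3, z_RORC), with
(1, 0) → 0 h, (0, 1) → 6 h, (−1, 0) → 12 h. Both genes are z-scored first
(raw log2 levels are positive and would confine the angle to one quadrant).
By construction the proxy pins the reference gene's peak at φ = 0, so it
coincides with anchored PCA phase at `anchor_peak_h=0.0`, not at the
default anchor.

**Transfer and metrics.** Paired tumor samples inherit the reconstructed
phase of their normal partner. Agreement between two phase sets is
summarized by a pairwise (Fisher–Lee-style) T-linear circular correlation,
`Σ_{i<j} sin(a_i−a_j)·sin(b_i−b_j)` normalized — chosen because
mean-centred circular correlation degenerates when phases cover the circle
uniformly, exactly the regime of an evenly sampled cohort — plus the median
absolute circular error (raw and offset-removed), wrapped to (−12, 12].

## Synthetic cohort generator

Rhythmic genes are pure 24 h cosines, `mesor + A·cos(2π(t−peak)/24)`, in
four groups peaking 0 h, 12 h, +6 h and −6 h from a reference peak (default
12.0 h, matching the anchored-orientation convention), with per-gene phase
jitter (SD 0.5 h), amplitudes U(0.5, 1.5), mesors U(4, 10) and additive
Gaussian noise (SD 0.25), all in log2 units. Background genes are constant
mesor plus noise. Defaults emulate a 24-sample, 2-hourly series; sampling
schemes: even (1+ cycles), uniform-random over 24 h, or a clinical daytime
window. The first genes of the relevant groups are aliased PER3, TEF
(0 h), ARNTL (12 h) and RORC (+6 h) and planted with zero jitter so
reference-gene operations see exactly the canonical geometry.

The tumor transform derives one paired sample per normal sample: rhythmic
amplitudes are multiplied by `amplitude_factor` (optionally only for listed
genes), listed genes are phase-shifted (mod 24), each tumor sample's
effective circadian time is jittered (default SD 2 h), and fresh noise is
drawn at the normal cohort's level from the tumor seed. Tumor matrices
carry no time annotation (snapshot semantics) but do carry the pairing.

**Realism limits.** Single sinusoidal harmonics (no waveform asymmetry), a
shared global noise level, Gaussian i.i.d. noise (no count overdispersion,
batch effects or gene–gene correlation beyond the planted rhythms), exactly
four discrete phase groups rather than a continuous phase distribution, and
amplitude-independent noise. The generator supports estimator validation
with known ground truth; it is not a transcriptome simulator.

## Fixtures

Packaged gene lists: a murine shared clock list (53 genes in-phase with
PER3, 52 anti-phase, 2 quadrature — RORC and CRY1 — 107 total), a
mammalian shared list conserved across mouse, baboon and human lung (9/3/1,
13 total), and five published clock lists shipped as flat symbol sets
(sizes 13, 12, 12, 12, 10). Cross-species matching is by upper-cased
symbol; list intersection requires group agreement, not mere co-presence.

## Determinism

Every stochastic step takes an explicit seed. The pipeline expands one
global seed into per-stage seeds via SHA-256 of `"{seed}:{stage}"`
truncated below 2³¹, so stages are independently reproducible; reports
embed the package version, seed and a config hash.

## Problem sizes exercised

Tests and the acceptance script use cohorts of 24 samples with up to 400
rhythmic + 700 background genes, 20-seed replication for all statistical
claims, and run in well under a minute in total on one CPU.
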