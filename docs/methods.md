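# Methods

This note documents the models, parameters and numerical choices behind
`mgpipe`: what the synthetic data emulates, how each analysis stage is
defined, and where design decisions were genuinely open.

## The biological setting

In the *Drosophila* mushroom-body calyx, olfactory projection neurons (PNs)
terminate in large presynaptic boutons that are enwrapped by dendritic
claws of Kenyon cells (KCs), forming ~5 µm synaptic units called
microglomeruli (MGs). A single GABAergic neuron, the anterior paired
lateral (APL) neuron, innervates the whole calyx and makes reciprocal
synapses with both PN boutons and KC claws. The package implements the
desk-scale analysis of this circuit: detection and quantification of
odour-evoked MG activity in two-photon calcium movies, comparison of
response-strength distributions across cell layers and inhibition states,
a volumetric analysis of how locally APL is activated, and an analysis of
APL's reciprocal synapse counts in a connectome-derived synapse table.

## Synthetic movie model

A movie is generated as

```
F(t, z, x) = B(x) · bleach(t) · (1 + Σ_i a_i(odour, z) · h(t − t_puff) · G_i(x)) + ε
```

- **Baseline** `B(x)`: a soft-edged elliptical "calyx" (bright, default
  1000 counts, ±20 % smooth heterogeneity) over a dim surround (300
  counts). Units are arbitrary photon counts in the regime of 16-bit
  two-photon acquisition; at 1000 counts the per-pixel per-frame noise is
  ≈3 % of baseline.
- **Transient kernel** `h`: difference of exponentials (rise τ = 0.2 s,
  decay τ = 1.0 s), normalized analytically to unit peak, so a unit with
  amplitude `a` peaks at exactly `a` (in continuous time). At 9 Hz
  sampling the discretely sampled peak is at most ~0.8 % below `a`; this
  is the dominant residual in the noiseless recovery checks.
- **Footprints** `G_i`: isotropic Gaussians with σ = diameter/4, i.e. the
  blob's visible extent (±2σ) spans the expected 5 µm MG diameter. A
  half-maximum-based width was rejected: at realistic densities the sum of
  footprint masses would tile the calyx and merge all active blobs into
  one plateau, which contradicts the punctate appearance of real bouton
  recordings (optical sectioning means only a fraction of the 3-D MG
  population is visible, and visible boutons do not interpenetrate).
- **Placement**: dart-throwing inside the ellipse with minimum centre
  spacing of one diameter (2× radius). Coverage is kept below the
  random-sequential-adsorption saturation (≈0.45 vs 0.547) so placement
  always terminates; the sampler restarts on dead ends.
- **Amplitudes**: log-normal per odour and per layer. Defaults encode the
  study conditions: PN boutons respond ~1.6× stronger to 3-octanol (Oct)
  than to 4-methylcyclohexanol (Mch) and weakest to δ-decalactone (median
  50 %, 80 %, 30 % ΔF/F₀, log-sd 0.4, half of MGs active per odour); KC
  claws under intact APL share one distribution for all odours (the
  normalization gain shifts every odour's log-mean onto their common
  mean); with APL output blocked the KC layer mirrors the PN contrast.
  The APL layer is a single diffuse unit filling the calyx mask, one draw
  per odour per fly (log-sd 0.15, reflecting that a whole-cell signal
  averages over many inputs).
- **Stimulus protocol**: 30 baseline samples, then 5 s odour puffs each
  preceded by 20 s of clean air, round-robin over the odour sequence.
  Planar sampling 9 Hz; volumetric 16 Hz split over 5 slices (3.2
  volumes/s). Odour-onset timing relative to acquisition start is
  configuration, not a constant.
- **Noise**: Gaussian with variance `gain·F + read²` (a Gaussian
  approximation to Poisson photon statistics, adequate at these counts),
  clipped at zero. **Bleaching**: exponential, default off. **Motion**:
  integer-pixel random walk clipped at a maximum drift; the walk starts
  after the baseline window, so the registration template epoch is
  motion-free by construction.

Volumetric movies multiply each unit's amplitude by a per-slice gradient
multiplier in (0, 1] (uniform, linear, or logistic in the 1-based slice
index). All ground truth — per-unit amplitudes and activity, slice
multipliers, expected slice profiles, motion walks, the baseline image —
is returned alongside the movie.

The synapse-table generator emits one row per synaptic connection between
the APL hub and PN/KC partners. The APL→neuron weight follows
`round(slope·w + intercept + ε)` on the neuron→APL weight (negative values
clipped to zero and counted); `noise_sd_for_r2` inverts
`r² = var(slope·w)/(var(slope·w)+σ²)` to hit a target population r².
Per-neuron compartment fractions are Beta-distributed (defaults: bouton
fraction mean 0.84; claw fractions 0.80/0.80/0.60 for γ, α′/β′ and α/β KC
subtypes). A configurable fraction of partners is one-directional or
absent from the calyx, and decoy rows carry a non-calyx region label so
the region filter does real work.

### What the generator does *not* emulate

No optics (PSF, scattering), no dendritic morphology, no spike-to-calcium
biophysics, no non-rigid motion, no correlated (structured) noise, no
overlap of MGs in depth. Passing tests therefore show that the analysis
recovers the statistical structure it assumes — not that it is robust to
every artefact of real recordings.

## Detection

The detector follows the minimum-image macro logic: per-pixel minimum
image over the whole recording → divisive normalization
`N = (F − M)/(M + eps)` → per-trial response image → Otsu threshold →
8-connected components per slice → keep components with area within
[0.25, 4] × the expected-diameter disc area.

Numerical choices:

- **eps** defaults to 0.25 × mean(M). This is a regularizing pedestal, not
  a guard: with a literal small eps, the darkest (out-of-tissue) pixels
  have the largest relative fluctuations and dominate the normalized
  stack. The pedestal scales with overall intensity, so detection remains
  invariant to multiplying the movie by a constant. An explicit small eps
  recovers the pure ΔF/F scale.
- **Response image** = temporal maximum over the trial window after a
  3-sample boxcar along time. A raw per-pixel maximum of ~45 noisy frames
  has a noise-inflated floor comparable to moderate signals; the short
  boxcar (≪ the 1 s decay) suppresses it with negligible amplitude loss.
  Thresholding one projection per trial (rather than per frame) yields one
  mask per odour exposure, and each puff is treated as its own trial.
- **Otsu** is computed on a 256-bin histogram over [min, max]; the
  returned value is the bin edge maximizing between-class variance, with
  exact ties (empty-gap plateaus of well-separated histograms) resolved to
  the centre of the tied plateau. Constant images raise a degenerate-input
  error, which the detector converts to an empty (valid) result.
- **No watershed splitting**: merged blobs either pass the area band as
  one component (and score against both true units by the
  centroid-within-one-radius rule) or are dropped and counted.
- The whole-calyx (APL) region and the per-slice volumetric regions use an
  automated policy: pixels above the Otsu threshold of the temporal-mean
  image, replacing a manually drawn ROI.

## Traces and summaries

F₀ is the mean of the first 30 samples of the recording (a global
baseline, not per-trial); ΔF/F₀ % is `100·(F − F₀)/F₀` on the unweighted
ROI-mean trace, and ΔF/F₀ %MAX is its raw within-trial maximum (no
smoothing; a smoothing window exists in configuration and defaults to
off). ROIs with non-positive F₀ are excluded and logged. The per-trial
summary is the mean of peaks over the trial's active ROIs (NaN when there
are none).

Because an ROI-mean over a blob dilutes the point peak, a correction
divides each peak by the baseline-weighted mean of the assumed Gaussian
footprint over the ROI's own mask (σ from the expected diameter, centre at
the ROI centroid, weights from the minimum image). On noiseless movies
this recovers amplitudes to < 1 %; at default noise the median relative
error is ≈ 5–10 %. Pooled peak distributions use raw (uncorrected) values
unless stated; the KS test is invariant to monotone rescaling, and the
correction varies slowly across ROIs.

## Statistics

- **Paired odour comparisons** (per-fly mean peak or active-ROI count) are
  normality-gated: D'Agostino–Pearson on the within-pair differences at
  α = 0.05 chooses between the paired t-test and the Wilcoxon
  matched-pairs test. Zero-variance differences produce a flagged
  degenerate report (p = 1 when all differences are zero). Under Gaussian
  nulls the gated procedure rejects at 5 % ± 2 % (checked at 1000
  replicates).
- **Distribution comparisons** pool per-ROI peaks across flies (fly
  identity retained for diagnostics; pooling across flies is a
  pseudo-replication trade-off made explicit) and use the two-sample
  Kolmogorov–Smirnov test on raw values; histogram binning is
  presentation-only.
- **Response distance**: per-fly Δ of mean peaks between odours, compared
  across odour pairs with a Welch-corrected unpaired t-test.
- **APL-silencing design**: two-factor (condition × odour) ANOVA on per-fly
  values with Tukey-HSD-adjusted within-condition odour contrasts.
- **Slope comparison** (volumetric): per-fly per-slice ratios enter a
  pooled OLS `ratio ~ slice × group`; the interaction t-test compares
  slopes. The slice index is the covariate (slopes read per section).
  Exact fits (zero residual) short-circuit to p ∈ {0, 1}. Per-fly ratio
  offsets do not bias the slope estimates but do inflate the residual
  variance, making the test conservative in that regime.

## Volumetric locality

Per fly, odour and slice, a whole-slice peak ΔF/F₀ is measured over the
slice's signal mask; profiles are averaged across animals first and the
odour-pair ratio taken second (ratio of means; mean-of-ratios is available
for sensitivity analysis). The default experiment contrasts a spatially
segregated pair (one odour's amplitude rising linearly across slices from
0.3× to 1×, the other uniform) against a colocalized pair (both uniform),
with 7 flies — the recovered segregated slope agrees with the analytic
expectation (E[ratio] × multiplier slope) to within a few percent on
average, and the interaction test detects the difference in essentially
every replicate.

## Connectome analysis

Rows are filtered to an exactly matching region label ("CA(R)" by
default). Reciprocal weights count rows per partner and direction; a
neuron "interacts" with APL only if both directions are non-zero, and
one-directional partners are reported separately (correlations default to
interacting partners; a flag includes all). r² is the squared Pearson
correlation of the two counts, identical to the OLS R² of the simple
regression. Compartment fractions are per-neuron fractions of hub→neuron
rows carrying a given tag ("unknown" rows drop out of the denominator);
the subtype comparison subsamples 70 neurons per KC subtype (seeded,
without replacement) before a one-way ANOVA with Tukey contrasts. The
manual two-rater blind scoring of synapse localization used on real data
is replaced by explicit compartment tags; no distance heuristic is applied
to untagged data.

## Problem sizes

Replicated experiments use scaled movies chosen once for desk-scale
runtime while keeping the stated stimulus timing and sampling: 112×112 px
fields with 30 MGs and one puff per odour for the planar replicates
(10 flies per layer, 20 replicate seed sets), 64×64 px five-slice volumes
for the locality replicates (7 flies, 50 replicates), and the full
176×176 px / 80 MG / two-puff movie for detection benchmarks. Null
calibrations run 1000 replicates at the statistics level. The synthetic
connectome audit uses study-scale tables (136 PNs, 1919 KCs, of which 126
and 1871 are reciprocally connected by construction).

## Known limitations

- Detection sensitivity on log-normal amplitude fields is ~0.7–0.9: the
  threshold detector misses the weak tail, exactly as a threshold-based
  macro does on real data. The quoted ≥0.9 benchmarks are for
  constant-amplitude fields.
- The KS test on pooled ROIs treats ROIs as independent; per-fly
  aggregates are available via the retained fly identities.
- Whole-slice APL measurements are diluted by the soft mask edge (measured
  Δ values are ~10–15 % below the generator's point amplitudes); ratios
  between odours are unaffected.
- The registration model is integer-translation only and shares one shift
  per volume.
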