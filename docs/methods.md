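# Methods

## Scope

`stavquant` implements four coupled pieces: a generative model for
two-channel fluorescence stacks and LFQ intensity tables
(`stavquant.scene`), line-profile granule quantification
(`stavquant.profiles`), antibody-accessibility scoring
(`stavquant.accessibility`), and the proximity-labelling LFQ enrichment
workflow (`stavquant.lfq`). The generative model is first-class code: every
downstream estimate is validated by parameter recovery against the ground
truth it emits.

## Image formation model

A scene is a set of emitters in physical coordinates (nm) inside a voxel
grid of shape (z, y, x) with calibration `pixel_size_xy` (default 65 nm —
a 6.5 µm camera pixel behind a 100× objective) and `z_step` (default
140 nm, stacks of ~50 slices).

**Granules** are spheres with uniform label density either throughout the
volume (streptavidin-like detection of a biotinylated interior) or in a
peripheral shell of thickness `shell_fraction × radius` (antibody-like
staining restricted to the granule surface); `shell_fraction = 1` reduces
exactly to volume mode. Rasterization deposits
`amplitude × (occupied fraction of the voxel)`, with the occupied fraction
estimated from 5³ sub-voxel centre samples. Five sub-samples per axis
(not 3) are used because the half-maximum diameter checks resolve widths to
a few hundredths of a pixel, and 3³ occupancy quantisation leaves a
radius-dependent bias of up to ~1% in the √3·r closed-form limit; at 5³
the residual is ≤0.3%.

**Nuclear pores** are point emitters evenly spaced on the mid-plane rim
circle of a nucleus, splatted trilinearly. Their default total brightness
(2×10⁴ photons) is chosen so that, after PSF spreading, a punctum's peak in
a sum projection stands an order of magnitude above the summed background —
the regime in which automatic (Otsu) mask construction is meaningful, and
visually comparable to well-stained pores. A per-channel scale map lets the
same geometry appear bright in the streptavidin channel and arbitrarily dim
in the antibody channel.

The optical pipeline per channel: convolve with a separable anisotropic
Gaussian PSF (`psf_sigma_xy` 110 nm, `psf_sigma_z` 320 nm — a widefield
approximation; no diffraction-accurate model), add constant background
(10 photons/voxel), then Poisson shot noise followed by additive Gaussian
read noise (SD 2). Noise streams are keyed by `(seed, channel label)`, so
renders are bit-reproducible and invariant to channel order; relabelling
channels permutes the stack and nothing else.

The replicated granule experiment (`simulate_granule_experiment`, default
3 replicates × 25 cells) renders one granule per cell (radius 500 nm,
shell fraction 0.25 for the antibody channel) with multiplicative
log-normal radius jitter at the replicate level (SD 0.10, emulating
starvation conditions varying between biological replicates) and smaller
per-cell jitter of radius and position. Default per-cell volumes are
24×96×96 voxels — large enough to contain the granule and its profile,
small enough that a 75-cell experiment renders in seconds.

## Diameter at 50% fluorescence

Projections are per-channel reductions over z; `sum` preserves total
intensity exactly and is the default for quantification. Granule detection
runs on the streptavidin channel (the channel that fills interiors):
Otsu-thresholded connected components ≥ 20 px, ranked by integrated
intensity, with intensity-weighted centroids — taking the first candidate
is the reproducible surrogate for manually picking "one of the larger
granules".

Profiles are sampled at 0.25 px spacing along a segment through the
centroid (configurable angle, default 0°), averaged over `width_px`
(default 3) parallel lines 1 px apart, with the *identical* segment reused
for every channel of a granule. Interpolation is an exact cubic spline
(`scipy.ndimage.map_coordinates`, order 3). Bilinear interpolation is
available (`interpolation_order=1`) but not default: its implicit triangle
kernel adds ~0.2 px² of smoothing variance, which systematically narrows
half-maximum widths by 1–4% at granule radii of 5–15 px, while the
interpolating spline leaves the √3·r limit accurate to <0.35%.

The 50% level is `baseline + 0.5·(max − baseline)` with the baseline
estimated as the mean of the lowest decile of samples — robust to diffuse
cytoplasmic background, and identical to half-of-max when the background is
zero (`baseline='zero'` switches to the latter). The diameter is the
distance between the *outermost* upward and downward crossings, each
linearly interpolated between bracketing samples. The outermost convention
is deliberate: a double-peaked shell profile must report the granule's
outer width, which is what "wider" means for peripheral staining. Profiles
whose level is not crossed on both sides of the maximum return no diameter
and the QC flag `unbounded`; flags propagate, so a quotient is only defined
when both channels have defined diameters.

Peak counting uses `scipy.signal.find_peaks` with prominence ≥
`fraction × (max − baseline)` (default 0.2). An optional moving-average
pre-smoothing is provided but defaults to window 1 (off): at the default
0.25 px sampling the prominence threshold already rejects noise spikes, and
any 3-sample average would merge the closely spaced double peaks the
statistic exists to detect on short profiles.

Replicate summaries report the mean and sample SD (n−1) of per-granule
quotients — the mean of quotients, not the ratio of mean diameters, since
the quotient is the per-granule observable — plus the fraction of profiles
with ≥2 peaks per channel. Both per-replicate and pooled summaries are
emitted, since "mean ± SD across granules" and "across replicate means" are
both legitimate readings of such data.

Maximum-signal statistics take the per-cell maximum of the sum projection
within the cell mask, fold change as ratio of group means, and an unpaired
two-tailed Student (equal-variance) t-test; Welch is a flag. Identical
groups short-circuit to t = 0, p = 1 rather than 0/0.

## Accessibility score

The reference mask is built from the streptavidin channel (Otsu by default,
explicit threshold or a nuclear-rim annulus optionally), the background
region is the sub-threshold area eroded by 2 px. Per cell,

    score = max(0, med(HA|mask) − med(HA|background)) /
            max(ε, med(strep|mask) − med(strep|background)),  ε = 1e−6

medians throughout for robustness to hot pixels and pore-to-pore
variability; ε guards against division blow-ups when the reference channel
carries no signal, in which case the cell is flagged instead of scored.
Scores aggregate as the median over cells (≥10 by default; fewer is
flagged) and are binned into half-open increment classes
`[edge_i, edge_{i+1})` with edges starting at 0 (default 0, 0.1, 0.5, 1.0);
a score exactly on an edge belongs to the upper class. The increments are
analysis configuration, not biology: the score makes a visual
colour-increment judgement computable, it does not claim a physical unit.

## LFQ enrichment workflow

Filtering keeps protein groups with at least one valid bait value (the
permissive convention appropriate when the control is expected to be
empty). Log2 transform rejects non-positive intensities by name; zeros in
MaxQuant-style input are read as missing. Imputation is per sample column:
with observed mean μ and SD σ (ddof = 1), missing cells draw from
Normal(μ − 1.8σ, (0.3σ)²) — the widely used downshifted-normal convention
for values below the detection limit; width and downshift are parameters.
Draws are keyed by `(seed, sample, protein)` so results are independent of
row/column order and byte-reproducible. Columns with <3 observed values
raise rather than impute from an unreliable σ.

Testing is an equal-variance Student t-test per protein group against the
untagged control triplicate, two-tailed; duplicate bait groups (n = 2) are
supported with df = 3. The effect size is the *t*-test difference
(mean log2 bait − mean log2 control). No multiple-testing correction is
applied to the mapped output — the map encodes effect-size increments, not
an FDR-thresholded hit list — but a Benjamini–Hochberg q-value column is
emitted for convenience. Degenerate rows (zero pooled variance) yield p = 1
when the difference is 0 and are flagged otherwise. Increment classes are
half-open intervals counted from 1, class 0 = "not enriched" below the
lowest edge (default edges 1, 2, 4, 6 in log2 units).

Component mapping joins results to a bundled parts list of trypanosome
nuclear-pore components and transport factors by gene ID or name synonym;
gene IDs are filled only where well established (e.g. exportin 1 =
Tb927.11.14340), other rows match by name. Components without a matching
result are "undetected"; results matching no component are listed as
unassigned.

The LFQ simulator draws per-protein base log2 intensities from
Normal(25, 2²) (typical MaxQuant LFQ scale), adds the group's true effect
and replicate noise (SD 0.3, a realistic replicate CV), and deletes cells
with logistic probability decreasing in intensity (midpoint 22.5, slope 1
per log2 unit, ≈15–20% overall — missing-not-at-random dropout near the
detection limit, the mechanism downshifted imputation assumes; midpoint
−∞ disables dropout).

## What the simulations do and do not show

The generator reproduces the *statistical structure* the analyses assume —
projected sphere geometry, shell-vs-volume label distributions, PSF blur,
shot noise, MNAR dropout — so passing tests demonstrate that the estimators
recover known truth under that model. They do not certify performance on
real micrographs, which add aspherical granules, spatially varying
background, chromatic misregistration, and manual granule choice, nor on
real LC-MS/MS data, whose missingness and variance structure is richer than
the logistic/normal model. Numerical results printed by the test-suite
experiments (e.g. mean quotients ≈1.25 at shell fraction 0.25) characterise
the synthetic conditions, not any particular biological measurement.

## Problem sizes and determinism

Test-suite and acceptance-script runs use desk-scale sizes chosen to keep a
full run in tens of seconds on one CPU: 48-slice stacks for the closed-form
checks, 3×25 cells for the replicated experiment, 60 cells per group for
fold-change recovery, 300–2000 simulated protein groups, 10⁴ imputation
draws, 12 simulated nuclei for accessibility recovery. All stochastic
stages take a seed and are reproducible bit-for-bit; stream keys derive
from `(seed, name)` pairs so results do not depend on evaluation order.

## Known limitations

- The Gaussian PSF is separable and shift-invariant; no Born–Wolf or
  vendor-specific model, no deconvolution.
- Diameters are 2D measurements on projections; no volumetric fitting.
- Granules are spheres; shell labelling is radially uniform.
- The accessibility score compares medians within a single mask; it does
  not model antibody penetration physics, and increment edges are user
  configuration.
- The LFQ model treats samples as independent columns; no peptide-level
  structure, shared-peptide ambiguity, or match-between-runs artefacts.
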