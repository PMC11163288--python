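# Methods

This note documents the models, procedures and numerical choices behind
`condenstat`, in the spirit of the methods documentation that accompanies
simulation and statistics packages: what is computed, under which
assumptions, and what the synthetic validation does and does not show.

## Segmentation procedure

Objects are detected by a background-referenced intensity threshold. The
reference frame is the one with the maximum mean cytoplasmic brightness
within the cell ROI (ties resolved to the earliest frame). Background mean
and sample SD (n−1 denominator) are measured in a cytoplasmic region free
of bright structures; the threshold is `mean + k·SD` with `k = 2.5` by
default, computed once on the reference frame and applied unchanged to all
frames of the analysis. Foreground is the strict inequality
`intensity > threshold` intersected with the ROI; connected components use
8-connectivity in 2D and 26-connectivity in 3D; components below 16 pixels
(2D) or 64 voxels (3D) are discarded and labels are renumbered
contiguously.

The two size filters are mutually consistent: 16 px of area 0.116 µm²
fixes the pixel size at √(0.116/16) = 85.1 nm, and with 250-nm optical
sections 0.116 µm³ is then exactly 64 voxels. `filter_consistency_counts`
reproduces both integers, and the generator's default pixel size is
0.0851 µm so that rendered scenes live on the same grid.

Because the original region selection is manual, the package substitutes a
deterministic proxy: the ROI is tiled into 2 × 2 µm squares, tiles whose
99th-percentile intensity stays below the ROI median + 1 SD (i.e. tiles
containing no bright object) are candidates, and the lowest-mean candidate
is chosen (fallback: lowest-mean tile). On synthetic cells this recovers
the true background mean within 1% and the SD within 10%.

Per-object measurements are reported in physical units: `area = n_px·p²`,
`volume = n_vox·p²·Δz`, equivalent radius of the equal-area disk or
equal-volume sphere, and circularity `4πA/P²` with the Crofton perimeter
estimate, which keeps rasterized disks within [0.9, 1.1] over the radius
range the analyses use. Integrated intensity is the sum of raw intensities
over the object's pixels, per channel.

## Size statistics and the cycle analysis

The per-cell size distribution is summarized by the empirical survival
function (CCDF) `P(S ≥ s)` evaluated at the observed sizes. Cross-cell
averaging evaluates each cell's survival function exactly at every point
of the union grid (the step rule: a cell with all aggregates above `s`
contributes 1 there) and reports the pointwise mean with
`SE = SD/√n_cells` — the cell, not the aggregate, is the replication
unit.

The condensation/dissolution cycle analysis segments the aggregate channel
at the first frame of each light-on interval (before any new interfacial
reorganization has occurred in that cycle) with the single
reference-frame threshold, and reports the mean area of aggregates below
the 5 µm² "small aggregate" cutoff per cycle, averaged across cells. The
10 µm² cutoff is used analogously to define "large aggregate" cells for
phase-diagram conditioning. Bulk conservation is checked with the
ROI-summed channel intensity normalized to frame 0.

## Interface profiling and colocalization

Radial profiles are accumulated per condensate in normalized radius
`r/R` with bin width 0.1 over [0, 2], averaged across condensates with an
SE; a condensate whose centre leaves the ROI is skipped with a warning.
Profiles are normalized per condensate to their own maximum by default
(a global-maximum and an unnormalized mode exist). An optional constant
background (typically the estimated cytoplasmic mean) is subtracted before
binning: with a realistic diffuse pool in the aggregate channel the
interfacial shell is a modest relative elevation of the raw intensity, and
subtracting the diffuse level is what makes the shell-to-interior contrast
interpretable.

"Physical contact" between an aggregate and a condensate/scaffold object
is operationalized as overlap or adjacency of the two masks after one
binary dilation with the 3 × 3 structuring element, and the Pearson
correlation is computed over the union of the two dilated masks — the
statistic is confined to the pair, not the whole cell. Zero variance in
either channel makes the PCC undefined and is flagged as such rather than
reported as 0. PCC is invariant under affine rescaling of either channel
by construction; this is property-tested.

## FRAP model

Recovery is modelled as a single exponential,
`F(t) = (1−d) + d·m·(1−e^{−k(t−t₀)})`, with the bleach depth `d` fixed
from the first post-bleach sample and `(m, k)` fitted by bounded least
squares (`m ∈ [0,1]`, `k ≥ 0`) over the post-bleach samples. One
exponential is the minimal model that distinguishes the three regimes the
analyses care about — no recovery (solid aggregates), partial recovery
(condensates with an immobile component), full recovery — without
asserting a transport mechanism; diffusion-model FRAP (Soumpasis/Axelrod)
is deliberately out of scope. A trace whose post-bleach rise is zero
returns `m = 0` with the rate flagged unidentifiable instead of an
arbitrary rate. No photofading correction is applied by default because
none is defined for the protocol; trace averaging interpolates linearly
onto the common time support when grids differ. Noise-free traces are
recovered to machine precision, the fit is exactly consistent under time
rescaling, and ensemble bias at noise SD 0.02 is below 1% for both
parameters (checked over 200 replicates).

## Phase mapping

Cytoplasmic intensities are measured in a ~10 µm² automatically selected
patch on the last frame before the first activation and converted to µM
through per-fluorophore linear calibrations (`(I − offset)/slope`)
determined by fluorescence correlation spectroscopy. The phase-diagram
axes are core concentration `C` (monomer concentration ÷ 24, the
stoichiometry of the ferritin 24-mer scaffold) and valence `V` (client
concentration per core, `c_client/C`). The valence-direction reading of
the ratio follows "average number of clients per core"; both raw
concentrations are retained so the inverse convention can be applied.

Condensation is classified from the first light-on interval: the ratio of
the ROI coefficient of variation (SD/mean) at the end of activation to its
pre-activation value must reach 1.5, and at least one detected object must
be droplet-like (circularity ≥ 0.8). Using the CV rather than the raw SD
makes the metric invariant to illumination gain. The cell-wide variant
requires at least two droplet-like objects and surfaces the raw droplet
count so either labelling convention of "cell-wide condensation" can be
applied downstream.

The binodal is fitted as a logistic decision surface in
`(log C, log V)`; when the two coefficients agree within 20% the boundary
is compatible with a product threshold `V·C = K` and
`K̂ = exp(−β₀/β̄)` is reported with `β̄` the mean of the two
log-coefficients (symmetric in the axes; identical to using either
coefficient within the agreement gate). A weak L2 penalty (C = 10³) keeps
the fit defined on perfectly separable titrations; the boundary location
is insensitive to it. Condition comparisons bootstrap cells within each
condition (1000 resamples by default, seeded), report the percentile 95%
CI of `log(K̂_b/K̂_a)`, call a shift when the CI excludes 0, and flag the
comparison when more than 10% of resamples are degenerate. On simulated
titrations of 400 cells the classifier reaches ≥ 95% accuracy, recovers
K within 25%, detects a fourfold threshold shift, and false-calls shifts
on null pairs at ≤ 10%.

## The synthetic-microscopy generator

The generator emulates the mechanistic picture the pipeline is meant to
measure, with exact ground truth:

- **Cell & background.** An elliptical cell on a 256 × 256 px frame
  (~21.8 µm across at 85.1 nm pixels), cytoplasmic background of mean 200
  and SD 20 intensity units added after PSF blur (noise is per-pixel, as
  in a detector).
- **Aggregates.** 60 solid disks with lognormal areas (median 0.18 µm²,
  σ_log 0.6), placed without overlap, rendered so each disk's integrated
  intensity is exactly proportional to its true area. The per-pixel
  amplitude (~100 units above background) is chosen so the mean + 2.5 SD
  threshold crosses a blurred object edge at its half-maximum, where the
  detected boundary coincides with the true edge; detected areas are then
  unbiased estimates of true areas rather than halo-inflated ones.
- **Condensates.** Four per condensation interval, nucleating at 0.4 µm
  radius at the start of each light-on interval, growing 0.15 µm/frame
  while the light is on, and decaying exponentially (τ = 1 frame) in the
  dark until dissolution. The default schedule is three
  condensation/dissolution cycles plus one final condensation round.
- **Interfacial capture.** From the frame after nucleation, any free
  aggregate whose centre is within 2.5 µm of a condensate rim is
  repositioned instantaneously to the nearest rim point and follows the
  rim as it moves. Capture is size-selective (< 1.5 µm²) and
  capacity-limited (6 aggregates per rim), reflecting the observed
  preference for small aggregates and the limited capacity of an
  interface for continued recruitment; no transport law is modelled
  because only the end state matters to the measurements.
- **Coalescence.** When a condensate dissolves, all rim-attached
  aggregates merge into one whose area (hence intensity) is the exact sum,
  placed at the intensity-weighted centroid; the lineage is recorded.
  With merging disabled, released aggregates instead redisperse with a
  1.2 µm rms displacement (consistent with free diffusion of sub-µm
  particles over a 15-min dark interval) without interpenetrating other
  aggregates — without this relaxation, rim-clustered aggregates fuse
  spuriously in the measured images and masquerade as coarsening in the
  merge-disabled control.
- **Optics.** Isotropic Gaussian PSF (σ = 0.10 µm) applied to the sharp
  scene, then background and Gaussian noise, then clipping at 0. Blur with
  reflective boundary conserves total intensity exactly; objects are kept
  ≥ 1 µm from the ROI edge so ROI-summed intensity is conserved to
  ~10⁻¹³ in noise-free renders.

Total aggregate signal is conserved by construction through every capture
and merge, the true mean small-aggregate area is non-decreasing across
cycles when merging is on, and identical parameters and seed give
bit-identical stacks.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: anisotropic/defocus PSFs, shot-noise
statistics, photobleaching during ordinary imaging, cell movement and
division, aggregate growth by monomer addition, partial wetting
geometries, and intra-condensate scaffold gradients. The validation shows
the pipeline measures the stated mechanism correctly when the mechanism
holds; it does not show the mechanism holds in any particular cell.

Auxiliary renderers serve the classifier and colocalization tests: a
pre/post activation response (uniform cytoplasm developing well-separated
circular droplets, ragged crosses for the irregular-recruitment case, or
nothing) and a contact-pair renderer whose scaffold/aggregate overlap is a
parameter, used to produce the size-dependent PCC trend.

## Problem sizes and runtime choices

Simulated validation uses 10 cells per condition for cycle analyses,
pooled condensates of 1–2 cells for radial profiles, 200 replicate traces
for FRAP bias, 400 cells per titration, 1000 bootstrap resamples for a
single condition comparison and 400 for each of the 10 null-calibration
repeats. These sizes put Monte-Carlo error comfortably below every margin
tested while keeping the full suite and the acceptance script in the
minutes range on one core.

## Known limitations

- The cycle analysis assumes the activation schedule is known exactly
  (carried by the stack's light schedule); it does not infer cycles from
  the images.
- The interpretable threshold K̂ exists only when the fitted boundary is
  close to a product threshold; strongly tilted binodals report
  coefficients but no K̂, and condition comparison then has no scalar
  summary.
- Circularity of near-filter-size objects (tens of pixels) is
  discretization-noisy; the droplet classifiers are reliable for droplets
  ≥ ~0.5 µm radius.
- 2D analyses use a single z-plane by default; a maximum-intensity
  projection is available but changes the meaning of "area".
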