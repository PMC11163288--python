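# condenstat

Quantitative image analysis of the interplay between liquid-like protein
condensates and solid protein aggregates in living cells, built around
optogenetic ("corelet") condensation experiments: p62 condensates whose
interfaces capture small polyQ aggregates and coarsen them through cycles
of condensation and dissolution, while large ubiquitinated aggregates
deplete free p62 and suppress further condensation.

The package provides every stage of that analysis as tested library code,
plus a synthetic-microscopy generator with exact ground truth so the whole
pipeline runs and is validated without any experimental data:

- **segmentation** — background-referenced intensity thresholding
  (cytoplasmic mean + 2.5 SD, measured in an automatically selected
  object-free region of the reference frame), 8-/26-connected components,
  minimum object size 16 px (0.116 µm²) in 2D or 64 voxels (0.116 µm³) in
  3D, and per-object statistics in physical units (area, volume, centroid,
  equivalent radius, circularity `4πA/P²`, per-channel integrated
  intensity).
- **size statistics** — per-cell complementary cumulative size
  distributions `P(S ≥ s)` averaged across cells with SE; aggregation
  propensity vs. concentration; mean small-aggregate (< 5 µm²) area at the
  first frame of each condensation cycle; bulk-intensity conservation
  traces.
- **interface & colocalization** — radial intensity profiles about
  condensate centres in normalized radius r/R (an interfacial shell peaks
  at r/R = 1); Pearson correlation between channels over the union of two
  1-px-dilated object masks for pairs in physical contact, binned by
  aggregate radius; integrated-intensity-vs-size curves normalized to
  channel maxima.
- **FRAP** — trace normalization to the first pre-bleach frame and
  single-exponential recovery fits
  `F(t) = (1−d) + d·m·(1−e^{−k(t−t₀)})` returning mobile fraction `m`
  and rate `k`, with the bleach depth `d` fixed from the first post-bleach
  sample; the no-recovery regime returns `m = 0` with `k` flagged
  unidentifiable.
- **phase diagrams** — FCS-calibrated conversion of cytoplasmic
  intensities to µM, phase points (core concentration `C` = monomer/24,
  valence `V` = clients per 24-mer core), condensation classification from
  the light response (coefficient-of-variation ratio plus droplet-like
  detected objects), logistic binodal fits in (log C, log V) with the
  interpretable product threshold `V·C = K`, and a seeded bootstrap test
  for boundary shifts between conditions.
- **synthetic microscopy** — calibrated two-channel time-lapses in which
  condensates nucleate and grow under blue light and dissolve in the dark,
  lognormal-sized aggregates adsorb to condensate rims and coalesce on
  dissolution (signal conserved exactly by construction), followed by
  Gaussian PSF blur and additive Gaussian noise; every event is recorded
  as ground truth.

## Worked example

```python
import numpy as np
from condenstat import SimParams, simulate_cell, cycle_coarsening, bulk_intensity_trace

stack, roi, truth = simulate_cell(SimParams(seed=2))   # 3 cycles + final round
report = cycle_coarsening(stack, roi)
print(np.round(report["mean_small_area_um2"].to_numpy(), 3))
# [0.273 0.393 0.6   0.746]
print(float(np.abs(bulk_intensity_trace(stack, roi, "polyQ") - 1).max()))
# 0.001152...
```

The first line is the mean area of small (< 5 µm²) aggregates at the
start of each condensation cycle: it roughly triples over three
condensation/dissolution cycles because rim-captured aggregates merge at
each dissolution. The second shows the bulk aggregate intensity stays
constant to ~0.1% — the coarsening is a reorganization of existing
material, not the creation of new signal.

The numbered scripts under `analysis/` run the full study — simulation,
segmentation and CCDFs, cycle coarsening (with a merge-disabled control),
radial/colocalization profiling, FRAP ensembles, and the phase-diagram
shift — writing tables under `results/` and large image stacks under
`scratch/`. A `condenstat` CLI exposes the same stages for use on real
TIFF stacks (`condenstat --help`).

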