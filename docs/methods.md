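# Methods

## The measurement model

Mosaic enhancer-reporter assays co-electroporate two plasmids into
presumptive limb tissue: a constitutive RFP (transfection control) and an
enhancer-driven GFP (reporter). Because delivery is patchy and dose varies
between embryos, raw GFP intensity is not comparable across embryos; the
assay's unit of measurement is instead

    relative activity = total GFP intensity / total RFP intensity

computed inside an anatomical mask. The package implements this estimator
exactly as a staged pipeline; every threshold and mask fraction it uses is
recorded in the output record so any number can be re-derived by hand.

### Pipeline stages and their numerical choices

- **Grayscale**: luminance weights (0.2125, 0.7154, 0.0721); identity on
  single-channel input; intensity range preserved (no rescaling to [0, 1]).
- **Bilateral denoise**: edge-preserving smoothing before any
  thresholding. Defaults: `sigma_spatial` = 3 px, `sigma_range` = 10% of
  the channel's dynamic range. The image is normalized internally for
  filtering and mapped back, so units are unchanged and a constant image
  passes through exactly.
- **Otsu threshold**: computed over the exact observed intensity values
  rather than a fixed 256-bin histogram, so the returned threshold is the
  exhaustive maximizer of the between-class variance w₀w₁(μ₀−μ₁)² for any
  input. Foreground is *strictly greater* than the threshold (ties go to
  background; deterministic tie-break toward the smallest maximizing
  threshold). All-equal input is a degenerate-input error.
- **Limb segmentation**: the Otsu foreground of the light image contains
  limb plus body wall; the annotated boundary polyline is burned into the
  foreground and 4-connected components are taken (4-connectivity so the
  8-connected drawn line cannot be leaked across). The limb is the
  component containing the annotated `limb_side_point`; an annotation that
  leaves a single component is an error.
- **Posterior and ZPA masks**: the biology defines these regions
  anatomically, not in pixels, so the package uses reproducible
  axis-aligned fractional crops of the limb bounding box along the
  annotated anterior–posterior and proximal–distal axes: Posterior keeps
  the posterior-most 50% (default), ZPA the intersection of the
  distal-most 40% and posterior-most 35% (defaults), clipped so the
  nesting ZPA ⊆ Posterior ⊆ Limb always holds. Orientation comes from the
  sidecar annotation, defaulting to top = anterior, right = distal (the
  standard dorsal mounting).
- **Transfection / activity regions**: Otsu is computed on the masked
  pixel values only — RFP within the analysis mask, then GFP within the
  transfected region. Constant RFP inside the mask means no transfection
  is detectable; the embryo is returned as an excluded, flagged record.
  Constant GFP is a *silent enhancer*, a valid outcome: an empty activity
  region with a logged warning.
- **Totals**: summed raw (denoised) intensities, with no background
  subtraction — the normalization is a plain ratio of totals. Whether
  intensity is summed over only the Otsu-foreground pixels (default) or
  over every pixel of the relevant mask is a config switch
  (`intensity_over`), and the choice is recorded in the record metadata.
- **Saturation**: channels with more than 1% of pixels at the saturation
  level are flagged, not excluded; exclusion policy is configuration, not
  hard-coded.

## The synthetic-data generator

The simulator emulates what the estimator needs to be tested against, not
optics: a limb bud as an ellipse beside a rectangular body-wall strip
(the simplest geometry that makes the manual-boundary step meaningful);
mosaic transfection as a Gaussian-smoothed white-noise field thresholded
at quantile 1 − `transfection_fraction` (correlation length
`transfection_patchiness`, default 6 px, reproducing patchy
electroporation without a cell model); a per-pixel plasmid dose in
[0.6, 1.0] from the same field, shared by both channels as in
co-electroporation; and an activity focus (default center (0.7, 0.7) in
limb-normalized AP×PD coordinates, radius 0.35) inside which clean GFP is
`activity_level` × the local RFP signal above background. Additive
Gaussian noise (`noise_sd`, default 2 intensity units ≈ 0.8% of the 8-bit
range) is applied per channel, then values are clipped to the bit-depth
range so saturation behaves like a camera. Default bit depth is 8
(configurable; the original acquisition hardware's depth is not
documented). One master seed drives a cohort; per-bundle seeds are master
seed + bundle index, so cohorts are bitwise reproducible and any single
bundle can be regenerated alone.

**Ground-truth activity.** The stored `true_activity` is the noise-free
relative activity the assay measures under the standard posterior-mask
convention: Σ clean GFP over the active region / Σ clean RFP over the
transfected region, both within the posterior half of the true limb. This
is deliberately *not* the per-cell ratio `activity_level`: with GFP summed
over the detected activity region and RFP over the whole transfected
region, the measurable quantity scales with the fraction of transfected
signal that is active. Defining truth at the assay level keeps
parameter-recovery checks well-posed for any focus geometry; the per-cell
level is echoed separately as `cell_activity_level`.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: optical blur and vignetting, autofluorescence
gradients, limb curvature and out-of-plane tissue, cell-scale intensity
granularity, annotation error in the manual boundary, and any correlation
between transfection dose and enhancer activity. Recovery numbers on
synthetic bundles bound algorithmic error, not biological or acquisition
error.

## PBM relative affinity

A factor's table maps every 8-mer to a median intensity; relative affinity
of 8-mer k is intensity(k) / intensity(optimal 8-mer) ∈ [0, 1]. Tables are
stored reverse-complement expanded (an 8-mer and its reverse complement
share one value — PBM signal is double-stranded), and collapsed input
tables are expanded on load. A binding site shorter or longer than 8 bp is
scored as the maximum relative affinity over all 8-base windows
overlapping the site by ≥ 6 bases (configurable: full containment or any
overlap); ties for the optimal 8-mer break lexicographically and are
flagged. Factors without PBM data yield an explicit NA row in the affinity
matrix, never a silent omission. The synthetic PBM landscape gives an
8-mer with m mismatches to the consensus (or its reverse complement,
whichever is fewer) expected intensity `optimal × decay^m`, with mean-one
multiplicative lognormal noise of coefficient of variation `noise_cv`
shared within each reverse-complement pair so symmetry is preserved.

## Construct bookkeeping and mutagenesis

Coordinates are 1-based inclusive at every interface (length =
end − start + 1), the convention under which the published enhancer
coordinates reproduce their printed lengths (1,373 bp chicken, 1,198 bp
human); BED input is converted on read. The bundled ZRS deletion-series
audit reports printed versus component-sum totals and deliberately leaves
the two published inconsistencies (F2: 309 printed vs 307 summed; F1F2:
1065 printed vs 996 summed) as reported discrepancies rather than picking
a side. Motif scanning reports all overlapping matches on both strands
(E-boxes and Hox sites can overlap); minus-strand hits are mapped to
plus-strand coordinates. In-silico mutagenesis is substitution-only,
enforces the 3–4 altered-core-base regime used for screening, and
verification mirrors bench screening: the destroyed motif may not survive
across mutated positions, the screening restriction site must be new, and
no forbidden motif may appear at a (position, strand) absent from the
original.

## Statistics

Rank-based tests are used throughout since group sizes are small and
normality is not assured: Kruskal–Wallis (tie-corrected, χ² approximation
with k−1 df; all-identical data is defined as H = 0, p = 1 with a
degenerate flag) with Dunn's post hoc z tests (tie correction
Σ(t³−t)/(12(N−1)); two-sided normal p; Bonferroni multiplier = number of
comparisons actually performed, clamped at 1), and Mann–Whitney U for two
groups. Dunn's test is implemented directly from the rank formulation and
cross-checked in the test suite against an independent transcription of
the formula. Mann–Whitney switches between exact enumeration over all
C(n₁+n₂, n₁) group assignments (tie-safe; used when both groups have ≤ 8
observations, where enumeration is cheap) and the tie-corrected,
continuity-corrected normal approximation; the two branches agree to
< 0.02 at the switch point. IQR outliers use type-7 (linear-interpolation)
quartiles and 1.5×IQR fences, are flagged and never removed. Significance
stars use strict thresholds, default scheme * < 0.05, ** < 0.005,
*** < 0.0005, **** < 0.0001, with a coarser `figure` preset
(0.01 / 0.001) selectable because published figure legends sometimes use
that convention.

## Pipeline and provenance

Runs are YAML configs validated by pydantic before any stage executes
(config errors exit before side effects). All outputs stay under
`output_root/run_id`; the append-only manifest records the config hash,
master seed, package version and a SHA-256 for every stage output, and the
JSON-line event log captures every threshold and mask fraction used, so
identical configs reproduce identical checksums and any activity record
can be re-derived by hand. Figures are written as PNG to keep outputs
byte-stable.

## Problem sizes used in tests and the acceptance script

Simulated frames are 96×80 px (geometry scaled proportionally from the
160×128 default), which preserves all pipeline behavior while keeping
cohort-scale simulations fast; the statistical power check runs 100
replicate two-group cohorts (n = 20 per group, activity 0.1 vs 0.8,
noise 6) through the full simulate → quantify → Mann–Whitney chain, and
calibration checks use 1000 null simulations. The acceptance script
re-runs the affinity oracle on 3 factors × 10 sites and the determinism
check on a 2×4-embryo pipeline.

## Known limitations

- The Posterior/ZPA masks are rectangular crops of the limb bounding box;
  real anatomical masks are curved. The fractions are configurable but the
  shape family is not.
- Site scoring uses the best 8-mer window; no position-weight-matrix or
  E-score modeling, and no prediction for factors lacking PBM data.
- The estimator's relative activity is mask-convention dependent; numbers
  are only comparable across embryos quantified with the same mask and
  `intensity_over` mode (both are recorded per record).
- Exact Mann–Whitney enumeration grows combinatorially; beyond 8 + 8
  observations the normal approximation is used by design.
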