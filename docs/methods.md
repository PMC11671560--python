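# Methods

`cle-afq` re-implements, as tested library code, a label-free confocal laser
endomicroscopy (CLE) autofluorescence analysis chain: synthetic frame
simulation with ground truth, automated frame exclusion, line-profile SNR
estimation with a paired filter comparison, detection and classification of
nine autofluorescence features, and per-case abundance summaries encoded as
Chernoff-face glyphs.  This note records the models, the tunable parameters
and their defaults, the numerical choices, and the limits of what the
synthetic validation can show.

## Frame geometry

The emulated device scans a 267 × 475 µm field of view into 1080 × 1920
16-bit pixels.  The two nominal axis ratios (267/1080 = 0.2472 µm/px and
475/1920 = 0.2474 µm/px) agree to better than 0.1%, so square pixels of
475/1920 ≈ 0.2474 µm are assumed; the long axis is used because it carries
the smaller rounding error.  Coordinates are 0-based, row-major, with the
origin at the center of the top-left pixel; object positions are stored in
µm and converted through `pixel_size_um`.

## Synthetic image formation (`cle_afq.simulate`)

Because no real recordings are openly deposited, a generator stands in for
them.  It does **not** model the fiber-bundle optics or fluorophore
spectra; it reproduces the image statistics the detectors care about:

- **Punctuate signals**: isotropic 2-D Gaussians with FWHM equal to the
  annotated diameter (1–3 µm).
- **Cells with fluorescent cytoplasm**: disks with a darker nucleus
  (45% of the radius at 25% amplitude) and a multiplicative granular
  texture on the cytoplasm (Gaussian random field, σ = 2 px, ±30%,
  clipped to [0.55, 1.45]).  The soft edge crosses half-maximum exactly at
  the nominal radius so diameters re-measured at half peak are unbiased.
- **Fibers**: smoothed random-walk polylines (step 3 px, heading
  s.d. 0.18 rad, reflected off the borders) stamped at the annotated width.
- **Round structures**: homogeneous disks, 10–60 µm, at weak contrast
  (default 3 background-noise s.d.), emulating psammoma-body-like objects.
- **Diffuse autofluorescence**: a smooth random field (correlation length
  ≈ 60 µm) spanning 0.5–1 × `diffuse_level` across the FOV, with three
  negative-contrast silhouettes (30–60 µm disks at 30% transmission).
- **Noise**: `pixels = poisson_scale · Poisson(mean / poisson_scale) +
  N(0, read_sigma²)`, so an object-free frame has variance
  `poisson_scale · mean + read_sigma²`.  The defaults
  (`poisson_scale = 0.1`, `read_sigma = 30`, `bp_background = 500`) put the
  sensor in a read-noise-dominated regime: σ changes by only ~1% when the
  longpass (LP) filter raises the background by the default 200 gray
  units.  This is the regime consistent with the paired-filter observation
  the pipeline is meant to reproduce — matched bandpass (BP)/LP frames of
  one scene show *no* systematic SNR difference even though the LP
  background is visibly brighter.
- **Contrast unit**: object amplitudes are specified in units of
  `sigma_ref = sqrt(poisson_scale · bp_background + read_sigma²)` (the BP
  background noise s.d., ≈ 30.8 at defaults; when noise is disabled for
  geometry tests, the default sensor model supplies the unit).  The
  default object contrast is 8 σ, the regime in which all detectors are
  expected to operate near ceiling; round structures default to 3 σ.

One root seed drives fixed per-purpose substreams (spots, small cells,
large cells, fibers, round, diffuse, BP noise, LP noise, artifacts), so
adding objects of one class never perturbs another class, positions are
drawn per object (count `n+1` extends count `n`), and renders are
bit-identical for a fixed (spec, filter, seed).  Overlaps are allowed
except fibers across round structures (rejection sampling, 10³ retries,
then a packing error); a spec whose total footprint exceeds the FOV area
is rejected outright.

**Autobrightness.** The real device ran with an unpublished autobrightness
algorithm.  The generator can linearly rescale the noise-free frame mean to
a target fraction of the dynamic range (5% when enabled), but this is *off*
by default: absolute background levels are part of several calibration
contracts (object-free frame mean, LP−BP offset recovery), and a default-on
rescale would silently break them.

**Artifacts.** `motion` convolves with a line kernel (length = strength in
px, random orientation) and adds 15% fresh read noise; `blank` replaces the
frame with its robust background plus noise; `duplicate` shifts by a random
sub-pixel offset (≤ strength px per axis) and adds 30% fresh read noise.

## Frame exclusion (`cle_afq.qc`)

The workflow this mirrors excluded frames by visual inspection.  The quantitative
surrogates, calibrated only on synthetic frames and making no claim of
equivalence to a human scorer's judgment:

- **No signal**: fraction of pixels above `median + k·(1.4826·MAD)` is
  below `min_frac` (defaults `k = 4`, `min_frac = 10⁻⁴`).  Median/MAD are
  used because bright objects bias mean and s.d.
- **Motion**: the median over a 6 × 6 tile grid of the structure-tensor
  eigenvalue ratio (gradients on a σ = 1.5 px smoothed frame), thresholded
  at 1.6.  A *global* mean-gradient outer-product was considered first but
  rejected: a single legitimate fiber dominates it and costs specificity,
  while a genuine smear is anisotropic in *every* tile.  Calibration on
  synthetic sets puts clean frames at ≈ 1.04 and 50 px smears at ≈ 4.9.
- **Duplicates**: per case, in acquisition order, each frame is compared
  against earlier kept frames by normalized cross-correlation after σ = 8
  px smoothing and 8× downsampling, over shifts up to 10% of the FOV;
  NCC ≥ 0.95 marks the later frame `duplicate_of` the best match.  The
  pre-smoothing is deliberate: it suppresses independent per-pixel noise so
  the correlation reflects shared scene content (duplicates score ≥ 0.96,
  independent scenes of identical statistics ≤ 0.5).
- **Precedence** is total: no_signal → motion → duplicate; a no-signal
  frame is never evaluated for motion, and only kept frames enter the
  duplicate comparison, which makes the pipeline idempotent and the
  duplicate graph acyclic.
- Blood contamination and out-of-focus areas are listed as unsupported
  categories: they are recognized failure modes but no operational criteria are defined here.

Tally percentages are rounded to the nearest integer (half away from
zero); when they do not sum to 100 the discrepancy is settled on the
largest fractional remainders.  `situ_category_summary` deliberately skips
the reconciliation — it reproduces how such tallies are conventionally
reported (53/141/73 of 338 → 16/42/22% with 71 frames left over).

## Line-profile SNR (`cle_afq.snr`)

Gray values are sampled along a segment at unit-pixel spacing (inclusive
endpoints, bilinear interpolation).  After allocation into signal and
background, `SNR = (mean(signal) − mean(background)) / s.d.(background)`.
The background s.d. uses the sample (n−1) form by default — background
segments can be short, and the protocol this follows did not specify the
form — with `ddof=0` available.  Automatic allocation uses Otsu's
threshold on the profile values (the original manual allocation is not
reproducible); manual labels remain first-class.

The paired BP-vs-LP comparison is a two-sided Wilcoxon signed-rank test.
Zero differences are dropped; |differences| are mid-ranked; for effective
n ≤ 25 the null distribution of W⁺ is enumerated exactly by dynamic
programming over the (doubled, hence integer) ranks, and the two-sided p
doubles the smaller tail, capped at 1.  Above n = 25 the tie-corrected
normal approximation is used.  An all-zero difference vector reports
W = 0, p = 1 with a degenerate flag.

The paired-filter study renders matched BP/LP pairs of one 3 µm object at
3 σ contrast (the SNR ≈ 3–5 regime in which such devices operate), labels
the transect geometrically (core → signal, beyond 10 px → background), and
is expected to produce a null result by construction, since amplitudes are
equal and only the background offset differs.

## Feature detection (`cle_afq.detect`)

The nine-feature *definitions* (1–3 µm spots, <25/≥25 µm cells, sparse <50
vs dense ≥50 spots, sparse <5 vs dense ≥5 cells, diffuse, fibers, round
structures) are applied exactly in the classification layer, which is a
pure function of counts.  A sparse flag requires at least one detection —
an empty frame is "none", not "sparse" — and a diameter of exactly 25 µm
counts as large.  The spot/cell routing boundary is >3 µm so spots and
cells partition the diameter axis.  Counts are raw per frame, no edge
correction; border-clipped objects count if their centroid is inside.

The detectors feeding those counts are this package's engineering and were
scored by eye in the workflow this mirrors; they are explicit surrogates:

- All detectors work on a z-scored frame: `(pixels − median) / σ_noise`,
  with σ_noise the robust s.d. of adjacent-pixel differences (objects are
  sparse and smooth structure cancels).  A background field — the grey
  opening of an 8× downsampled copy with a 160 px radius disk — is
  subtracted first; compact objects cannot survive the opening, while
  diffuse AF (correlation length ≈ 240 px) largely remains in the
  background and is flattened away.
- **Spots**: scale-normalized Laplacian-of-Gaussian over six scales
  matching 1–3 µm FWHM, maximum across scale, local maxima above 1.5
  (noise units), non-max suppression within ≈ one spot radius.  Each
  candidate's diameter is re-measured from the half-max region (corrected
  for the σ = 1 px measurement smoothing); candidates leaving [1, 3] µm by
  more than one pixel are dropped.
- **Cells**: threshold at 4.5 σ on a smoothed frame, morphological closing
  and hole filling, connected components.  Components are rejected when
  spot-sized (≤3 µm), strongly elongated (aspect ≥ 5 → fiber), far from
  convex (solidity < 0.65 → curved fiber), or when a <8 µm component's
  eroded core decomposes into spot-sized pieces (→ merged spot cluster,
  the package's operational answer to the granular-cytoplasm-vs-spot-
  cluster ambiguity).  Large (≥25 µm) components must additionally show
  granular texture (internal CV ≥ 0.12) — homogeneous large blobs are
  round structures, not cells.
- **Fibers**: Sato ridge filter on a 2× downsampled frame at scales for
  1–4 µm widths, threshold 2.0, skeletonization; skeleton components
  shorter than 25 µm or with length/width < 5 are dropped (which also
  subsumes the 10 µm branch-pruning scale).  Skeleton length = pixel count
  × 1.12 (diagonal-step correction).
- **Round structures**: LoG blob detection on a smoothed 4× downsampled
  frame at 10–60 µm scales; candidates survive when the interior median
  sits between 1 and 6 σ and the interior is homogeneous after removing a
  fitted plane (percentile-based spread / median ≤ 0.15 — plane removal
  tolerates residual diffuse gradients, percentiles tolerate an
  overlapping spot).
- **Diffuse AF**: discrete objects are masked, the rest is low-pass
  filtered (masked normalized convolution, σ ≈ 48 px); coverage is the FOV
  fraction where the low-pass field exceeds its 2nd percentile by more
  than 0.5 σ, and the flag fires at coverage ≥ 0.5.
- `analyze_frame` orders the detectors so cell masks veto spot and fiber
  detections inside cytoplasm and fiber support vetoes spot detections
  along ridges.

All thresholds live in `DetectorParams` (YAML-serializable); the defaults
were calibrated once on the synthetic suite at default contrast.

## Aggregation and glyphs (`cle_afq.cohort`)

A case's abundance per feature is `100 × (frames with flag) / (analyzable
frames)`; QC-excluded frames never enter.  Per-tumor-type medians are
medians of case-level percentages.

Each case becomes a Chernoff face.  The feature-to-slot assignment is
fixed (face size ← sparse punctuate; forehead/jaw arc ← diffuse; forehead
shape ← fibers; jaw shape ← dense punctuate; eye angle ← round structures;
pupil direction ← sparse small cells; nose length ← dense large cells;
mouth shape ← dense small cells; mouth arc ← sparse large cells); every
mapped parameter is `pct / 100`, unmapped parameters are fixed at 0.5 —
the conventional face renderers leave the default value unspecified, 0.5 is this
package's convention.  The face geometry itself is an original
parameterization (two half-ellipses joined at an equator set by the
forehead/jaw arc parameter, rotated elliptical eyes, sliding pupils, a
vertical nose segment, a parabolic mouth), documented in
`cohort._draw_face`.  SVG output is deterministic (fixed hash salt, no
timestamp); specs that differ in any one parameter render differently.
The `GlyphSpec` carries its source percentages so the pct → spec → pct
round trip is exact rather than accurate to a unit in the last place.

## Validation design and problem sizes

The reference per-patient abundances and SNR medians were measured on
patient images that are not available, so the validation is structural:

- reference *arithmetic* that is self-contained (the in situ category tally)
  is reproduced exactly;
- the SNR estimator is checked against a hand-computed profile and for
  consistency (mean |error| < 10% of the true Δµ/σ at 200 background
  samples, 500 replicates);
- the exact Wilcoxon implementation is checked against brute-force sign
  enumeration (all n ≤ 10) and against an independent library
  implementation in the tie-free exact and large-n regimes;
- the paired-filter null is reproduced on 20 cohorts of 50 matched pairs;
- detector recovery is scored on 100 randomized frames (nine-flag
  agreement ≥ 85%, punctuate flags ≥ 95%) and QC flags on 300 labeled
  frames (sensitivity and specificity ≥ 0.95 each).

Randomized benchmark scenes draw counts with a margin to the sparse/dense
boundaries (spots from {0} ∪ [1,45] ∪ [55,110], cells from {0..3} ∪
{6..9}): at the boundary the correct flag is undefined under an
unavoidable ±1–2 counting error, so boundary exactness is tested
separately at the classification layer, where it is a pure function.

Problem sizes (frames per benchmark, pairs per cohort) were chosen so the
whole validation runs comfortably on a single CPU; they can be scaled up
through the function arguments.

## Known limitations

- The generator's object appearance and the device's autobrightness and
  background statistics are plausible constructions, not fitted to real
  data; passing tests demonstrate internal consistency of the pipeline,
  not human-level scoring of real tissue.
- Detector thresholds are calibrated at the default 8 σ contrast; at
  substantially lower contrast recall degrades before the QC no-signal
  flag fires.
- Blood contamination and out-of-focus exclusion are unimplemented
  (no operational criteria defined); vessels render only as an optional negative
  contrast and have no detector.
- Tumor-type inference is out of scope by design: with a handful of cases
  per type only descriptive summaries (medians, glyphs) are produced.
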