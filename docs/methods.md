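# Methods

`conetop` quantifies cone survival across a flat-mounted retina the way it
is done at the bench for cone-opsin-stained whole mounts of degenerating
(rd10-like) mice: a low-power montage shows bright cone-rich areas
alternating with dark degenerating zones; isodensity curves traced on that
brightness map partition the mount into strata; absolute densities are
measured on a few high-resolution confocal fields placed along the two
principal meridians; and the whole-mount total is the area-weighted sum of
the stratum densities.  Because no raw micrographs are deposited for this
kind of study, the package ships a calibrated synthetic-retina generator
with known ground truth, so every stage is validated by parameter
recovery rather than by eye.

## The stratified estimator

Let the outline be partitioned into disjoint isodensity regions
$R_1,\dots,R_n$ (dark → bright) with areas $A_i$ (mm², by pixel counting ×
scale²).  Each region receives at least one of 16 sampling locations
spaced along the dorso-ventral and naso-temporal meridians; at every
location two 125×125 µm² fields are imaged and counted, and the location
density is their mean.  With $\hat d_i$ the mean location density inside
region $i$,

$$\hat N \;=\; \sum_{i=1}^{n} \hat d_i \, A_i .$$

The 32 fields cover $32 \times 0.015625 = 0.5$ mm²; against the default
whole-mount model (a disc of radius 2.05 mm, area ≈ 13.2 mm²) that is a
sampling fraction of ≈ 3.8%.  Totals can be expressed as a percentage of
the wildtype cone population (reference constant 180,000, configurable);
the raw ratio is always reported alongside the rounded percent.

If the true density field is constant within each region and the location
densities equal those constants, $\hat N$ equals the integral of the
density exactly (a property test asserts this).  For smooth density
fields the residual error is stratification bias plus Poisson sampling
noise; over 50 seeded degenerate mosaics the mean signed error is within
±5% and single runs stay within ±15% (both asserted).

### Sampling-scheme placement

The two meridians give four half-meridians; each carries four locations
evenly spaced between an inner bound and the margin (edge clearance
100 µm keeps fields on tissue).  The four half-meridians are
phase-staggered by a quarter of the spacing step, so the union of the 16
radii covers the radial span densely — with identical radii on every
half-meridian, a five-level radial partition would leave a middle annulus
unsampled, and no perpendicular shift can fix a radial miss.  After
placement, locations are shifted perpendicular to their meridian (≤200 µm)
until every region holds at least one; an unreachable region is a hard
error rather than silent imputation, so scheme failures surface.

The inner bound is the estimated cone-free-zone radius plus a 340 µm
clearance.  The clearance was chosen from the model, not tuned on test
outcomes: the innermost location should sit far enough outside the
degeneration border that its expected field density overshoots the
profile floor `d_min` by roughly the downward bias of the
minimum-over-locations statistic (about one Poisson standard deviation of
a two-field count at 3,000 cones/mm², ≈10%), so that the lowest measured
location density is centred on `d_min`.  The two fields of a location sit
side by side, offset ±70 µm perpendicular to the meridian, keeping both
at the same eccentricity.

## Synthetic whole mounts

The generator emulates the study conditions, not any particular retina:

* **Geometry** — a disc of radius 2.05 mm (≈13.2 mm²), retina-centred mm
  coordinates, x nasal, y dorsal.  Relief cuts are not modelled.
* **Density profiles** — degenerate presets carry a central cone-free zone
  (scotoma; radius 0.5 mm for the standard-housing preset, 0.3 mm for the
  enriched one) and a monotone radial rise from `d_min` at the scotoma
  border to `d_max` at the margin, spanning the reported per-retina
  ranges: 3,000–50,000 cones/mm² (standard housing) and 4,000–85,000
  (enriched).  The radial form is a squared quintic smoothstep: flat just
  outside the border, where the centre-to-periphery wave of degeneration
  has most recently passed, then rising steeply toward the spared far
  periphery.  The true radial law is not known; this is an explicit
  modelling choice.  Local anisotropy is modelled by an angular exponent
  modulation $b^{\,1+a\cos 2\theta}$ (default $a=0.3$ for the degenerate
  presets) that bends the mid-profile without moving the endpoints.  The
  wildtype preset is a shallow 12,000–16,000 gradient with no scotoma
  (total ≈ 190k, consistent with the 180k reference).
* **Point process** — inhomogeneous Poisson with the profile as intensity,
  thinned to a hard-core minimum spacing (default 1.0 µm) by sequential
  inhibition.  Thinned points are replaced by local jitter (≤50 µm, with
  a density-ratio acceptance), so the expected count equals the density
  integral and the *local* intensity is preserved — a global redraw would
  drift points from dense to sparse zones and bias the inner densities by
  several percent.  A packing feasibility check rejects exclusion radii
  that cannot carry the peak density (random-sequential-adsorption
  jamming bound with a factor-2 safety margin); at 85,000 cones/mm² the
  practical limit is ≈ 1.5 µm, which is why the default exclusion is
  1.0 µm.
* **Field rendering** — each cone is an isotropic Gaussian spot
  (σ = 1.2 µm, unit peak) at 0.25 µm/pixel on a constant background (0.1)
  with additive Gaussian read noise at peak-SNR 10.  Cone positions are
  binned to the pixel grid (≤0.18 µm quantisation, well below the 1 µm
  localisation tolerance).
* **Montage rendering** — cone counts binned at 10 µm/pixel, smoothed at
  20 µm, normalised so dense areas sit near 1, plus background and read
  noise.  Montage brightness is therefore a strictly monotone proxy of
  local density (window-averaged Spearman ρ > 0.95 asserted), which is
  all the partition needs: absolute densities come from the fields.

What the generator does **not** emulate: staining artefacts (uneven
labelling, folds, bleaching), rods, the two cone classes, relief cuts,
real mosaic regularity beyond a hard core, and montage stitching seams.
Passing recovery tests therefore demonstrate correctness of the
*pipeline* under the stated imaging model, not robustness to every
real-world artefact.

## Brightness map and isodensity partition

The montage is background-corrected and smoothed (masked normalised
Gaussian, FWHM 100 µm).  The default background correction subtracts a
constant robust dark level (0.5th percentile of a denoised copy): a
constant shift never disturbs the brightness *ordering* that the
partition is built on.  A rolling-ball-style grey-opening mode
(window 500 µm) is available for montages with genuine slow staining or
illumination gradients, but on montages whose signal itself varies at
those scales the opening envelope tracks the signal and distorts the
profile, so it is not the default.

Isodensity levels are quantile (equal-pixel-mass) bins of the masked map,
ordered dark → bright, with cuts snapped to midpoints between distinct
intensity values so that heavily tied maps (e.g. step images) still
produce non-empty bins with boundaries between the plateaus.  Five levels
are the default; the count is a config knob and the partition invariants
(disjoint, exhaustive, exact pixel-area conservation) hold for any count.
Regions may be multiply connected.  Boundary polylines are exportable as
GeoJSON in mm coordinates.

The cone-free-zone radius is estimated as the equivalent radius of the
near-zero-brightness connected component containing the retinal centre
(threshold 3% of the 99th-percentile map value — about half of the
`d_min`/`d_max` brightness ratio of the sparsest preset, so the crossing
of the blurred dark edge lands on the border).  On the degenerate presets
the estimate is accurate to ±0.05 mm; a healthy topography returns 0.

## Spot detection: matched peeling

Cone outer segments appear as near-identical blurred spots, so detection
is posed as greedy matched peeling (a CLEAN-style matching pursuit)
rather than the classic band-pass + local-maxima + watershed chain.  The
image is matched-filtered (slight smoothing), then unit-amplitude
template spots are subtracted one at a time from the running residual at
its current maximum until no candidate exceeds `floor_rel` (default 0.5)
times the single-spot amplitude.  Every subtraction removes exactly one
cone's flux, so the count remains accurate deep into the overlap regime —
at 85,000 cones/mm² the median nearest-neighbour spacing (~1.9 µm) is
below the two-maxima resolution limit (2σ = 2.4 µm) and any
maxima-counting detector undercounts by ≥30%, while peeling stays within
a few percent.  Declumping is implicit; an area gate on connected
foreground components rejects sub-resolution noise (<1 µm² per spot) and
isolated oversized debris (>20 µm²).  Positions are refined to sub-pixel
by local centroids; detections hugging the frame edge (<0.4 µm) are
dropped because their true centre may lie outside the field
(centre-inside counting; the residual bias is below 1%).

Two acquisition constants matter: the **background (black) level** and
the **single-spot amplitude**.  Both are calibrated once per retina
(imaging session) from the dimmest fields, where most pixels are pure
background and spots are isolated: the black level as the smallest
per-field median, the amplitude as the median isolated-maximum height.
This mirrors bench practice (black level and gain are set per session)
and matters quantitatively: a per-field median background is biased by
the signal plateau in dense fields and would cost ~30% of the count at
the top densities.  Per-field fallbacks keep `detect_cones` usable on a
single image.  All thresholds are relative to image statistics, so
detection is invariant to uniform intensity rescaling.

Calibrated on the synthetic renders, the median count error across 20
seeded fields is within ±5% at 3,000, 50,000 and 85,000 cones/mm² at the
default SNR, with 100% recall and precision on noiseless, well-separated
spots.  The proprietary routine the procedure replaces published no
parameters, so these defaults are anchored to the synthetic imaging model
only.

## Companion measurements

* **ERG b-wave** — exactly five sweeps per flash luminance are averaged
  pointwise; the amplitude is the post-stimulus maximum minus the mean of
  a pre-flash baseline window (default 20 ms; the acquisition band-pass
  is assumed already applied).  The amplitude is signed and invariant to
  constant offsets.
* **Water-task thresholds** — success rate must be *strictly above* the
  0.70 criterion (literal reading of "above 70%").  Scanning from the
  easiest level toward the hardest, the threshold is the most extreme
  level passed before the first failure, so every easier tested level
  must also pass; no interpolation between tested levels.  Acuity scans
  low→high spatial frequency; contrast scans high→low contrast.  If even
  the easiest level fails, the threshold is `None`.
* **ΔΔCt** — ΔCt = mean target Ct − mean reference-gene Ct over exactly
  triplicate wells; ΔΔCt subtracts the calibrator group's ΔCt (enriched
  normalised to standard housing); Rq = 2^(−ΔΔCt) with the usual
  100%-efficiency assumption.  Replicate SD above 0.5 cycles flags the
  result without dropping it.
* **Densitometry** — band density divided by its loading-control band;
  groups compared as percent difference of means.

## Numerical choices and degenerate inputs

Raster areas are always pixel counts × scale² (partition areas conserve
the outline area exactly, in pixel units).  Rasters use the pixel-centre
convention.  A constant brightness map thresholds to all-foreground with
a warning; requesting more levels than distinct intensities is an error;
a saturated or empty field is flagged on the sample, not raised, and a
flagged field is dropped from its location mean with the flag propagated.
Identical seeds reproduce identical mosaics, images and summaries
bit-for-bit; all randomness flows from `numpy` PCG64 generators seeded
from the run seed.

## Validation protocol and problem sizes

Parameter-recovery checks run the full image-based pipeline on 15 seeded
whole mounts per housing condition — the study's per-condition whole-mount
count — and compare the mean of the per-retina minimum and maximum
location densities with the profile extremes (±10% sparse condition,
±15% enriched, whose top densities sit in the spot-overlap regime).  A
single retina's minimum is a noisy statistic (Poisson SD of a two-field
count at 3,000 cones/mm² is ~10%), which is why the protocol, like the
study, averages across retinas.  The estimator-bias property (50 seeds)
reads field counts from ground-truth coordinates instead of rendered
images, isolating sampling/stratification bias from detection error; the
detection error is bounded separately by the field-level benchmarks.

## Known limitations

* The radial density law and the anisotropy model are modelling choices;
  only the density extremes, the scotoma topology and the montage
  brightness–density monotonicity are anchored to reported observations.
* Synthetic whole-mount *totals* follow from the monotone radial profile
  and are larger than the reported per-retina totals, which arose from
  real topographies where high densities occupy small patches; recovery
  is therefore always assessed against the generator's own ground truth.
* Session calibration of the detector assumes at least one
  background-dominated (sparse) field per retina; a uniformly dense
  retina falls back to a biased per-field amplitude estimate.
* The scotoma-radius estimator assumes the cone-free zone contains the
  retinal centre.
* No confidence intervals on the per-retina total are produced; the
  study design compares means across animals.
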