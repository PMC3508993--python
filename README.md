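# conetop

Quantifying cone photoreceptor survival across a retinal whole mount.

In retinal degenerations such as retinitis pigmentosa (modelled in the
rd10 mouse), cones die in a centre-to-periphery wave, leaving a retina
with a central cone-free zone and strongly anisotropic residual
topography — bright cone-rich areas alternating with dark degenerating
zones on an opsin-stained flat mount.  A single "mean density × area"
number badly misrepresents such a retina.  `conetop` implements the
stratified counting procedure used for this situation, end to end:

1. **Brightness map** — the low-power whole-mount montage is
   background-corrected and smoothed; local brightness is a monotone
   proxy of local cone density.
2. **Isodensity partition** — the map is divided into ordered isodensity
   regions $R_1,\dots,R_n$ (default $n=5$, quantile levels); the traced
   boundary curves are exportable as GeoJSON.
3. **Meridian field sampling** — two 125×125 µm² high-resolution fields
   at each of 16 locations along the dorso-ventral and naso-temporal
   meridians, placed so every region is sampled (≈3.8% of the surface).
4. **Spot detection** — cones are counted per field by matched peeling
   (a CLEAN-style matching pursuit of unit-amplitude spots), accurate
   from 3,000 to 85,000 cones/mm², i.e. deep into the spot-overlap
   regime.
5. **Stratified total** — with region densities $\hat d_i$ (mean over the
   locations inside each region) and areas $A_i$:

   $$\hat N = \sum_i \hat d_i A_i,$$

   reported with the sampling fraction and, optionally, as a percent of
   the wildtype cone population (reference 180,000, configurable).

Because raw micrographs for such studies are typically not deposited, the
package includes a first-class **synthetic-retina generator**: calibrated
whole mounts with known ground-truth cone coordinates, a central
cone-free zone, densities spanning the reported ranges of
standard-housed (3,000–50,000 cones/mm²) and environmentally enriched
(4,000–85,000 cones/mm²) degenerate retinas, hard-core mosaic spacing,
and diffraction-blurred spot rendering with read noise.  Every pipeline
stage is validated by parameter recovery against this ground truth.

Companion measurement rules from the same experimental programme are
included: flash-ERG b-wave amplitude (baseline-to-peak after 5-sweep
averaging), visual water-task thresholds at the strict >70% success
criterion (acuity and contrast sensitivity), ΔΔCt relative qPCR
quantification (2^(−ΔΔCt), triplicates, reference gene, calibrator
group), and loading-control-normalised blot densitometry.

## Worked example

Simulate a standard-housing degenerate retina and run the full pipeline:

```python
from conetop import make_density_profile, sample_mosaic
from conetop.pipeline import analyze_mosaic

profile = make_density_profile("rd10_st")      # 3,000-50,000 cones/mm²
truth = sample_mosaic(profile, seed=1)
result = analyze_mosaic(truth)

est = result.estimate
print(f"true total      {truth.true_total}")
print(f"estimated total {est.total:.0f}")
print(f"sampling fraction {est.sampling_fraction:.2f} %")
print(f"scotoma radius estimate {result.scotoma_radius:.3f} mm")
print(f"location densities {result.location_densities.min():.0f}"
      f"-{result.location_densities.max():.0f} cones/mm²")
```

prints

```
true total      344253
estimated total 346915
sampling fraction 3.79 %
scotoma radius estimate 0.509 mm
location densities 2176-49984 cones/mm²
```

The estimate recovers the ground-truth total within 0.8% from counts on
3.79% of the surface; the measured location densities span the profile's
3,000–50,000 cones/mm² range (the lowest location sits near the
degeneration border, where a two-field count at 3,000 cones/mm² carries
~10% Poisson noise); and the cone-free-zone radius is recovered to
0.01 mm.  The same run writes `estimate.csv` (per-region density, area,
contribution), `locations.csv`, `summary.json`, isodensity curves as
GeoJSON and a QC overlay via `conetop.pipeline.write_report`.

The same flow from the shell:

```sh
conetop simulate --profile rd10_st --seed 1 --out run/sim
conetop map      --montage run/sim/montage.tif --levels 5 --out run/map
conetop count-fields --fields run/sim --out run/fields.csv
conetop estimate --partition run/map --fields run/fields.csv --out run/est
# or everything at once, from a YAML config:
conetop run --profile rd10_st --seed 1 --out run/full
```

Companion metrics: `conetop metrics erg|behaviour|qpcr|blot --input …`.

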