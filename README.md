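# lqli — linear quantification of lymphoid infiltration

Lymphocyte density within and around solid tumors is a strong prognostic
marker, but it is spatially very heterogeneous: a single count on a small
field (such as a 0.6 mm tissue-microarray core) is an unreliable estimate
for the whole tumor. `lqli` implements an automated, reproducible
alternative for pathologists and image-analysis researchers: lymphocyte
density is expressed as a *curve* over signed distance from the tumor's
invasive front, and tumors are classified by the shape of that curve
rather than by any single count.

## The method

On an IHC-stained slide (DAB-brown positive lymphocytes, hematoxylin-blue
counterstain) a rectangle of W = 1 mm × L = 4 mm (4 mm², more than 14
times the area of a TMA core) is anchored on the annotated invasive front,
its long axis perpendicular to the front, with the front at the middle of
the axis and the tumor on the inner half. Stain-positive cells are
detected in three steps — color thresholding, watershed splitting of
touching cells, and size filtering (tunables: size bounds, blue intensity,
red intensity) — and counted in Δ = 5 μm segments of the axis. Counts are
standardized to a 1 mm-wide strip, so each value is a density per
Δ·W = 5000 μm². Curves from 2–8 rectangles along the front are averaged
into a mean curve d(v), v ∈ [0, 4000] μm with the front at v = 2000.

The smoothed mean curve is assigned one of three infiltration patterns:

* **pattern 1** — high density within the tumor relative to its
  surroundings;
* **pattern 2** — a prominent density peak near the invasive margin
  (typically a few hundred μm on the host side);
* **pattern 3** — uniformly low density.

An explicit rule cascade (intratumoral mean ≥ τ and dominance ρ → 1;
else margin peak ≥ τ and prominence π over the flank baseline → 2;
else 3) replaces visual curve reading, so every call is reproducible and
auditable. Cohort utilities compute pattern frequencies, dual-marker
concordance and Cohen's κ for interobserver agreement. A synthetic-slide
generator renders brown-cell/blue-background images from inhomogeneous
Poisson point processes with the three archetype intensities, with
ground-truth centroids and labels, so the whole pipeline is testable
without histology data.

## Worked example

```python
from lqli import (default_config, simulate_slide, detect_cells,
                  bin_counts, to_density, classify, minmax_ratio)

truth = simulate_slide(default_config(2), seed=7)   # pattern-2 margin peak
dets = detect_cells(truth.image, truth.roi)
profile = to_density(bin_counts(dets, truth.roi), truth.roi)
call = classify(profile)
het = minmax_ratio(profile, window=(2000, 4000))
print(f"true pattern: {truth.true_pattern}, cells rendered: {len(truth.centroids)}")
print(f"cells detected: {len(dets)}")
print(f"called pattern: {call.pattern} ({call.rule_fired})")
print(f"peak: {call.peak_height:.1f} cells/5000 um^2 at {call.peak_offset_um:+.0f} um from the front")
```

prints

```
true pattern: 2, cells rendered: 1740
cells detected: 1719
called pattern: 2 (margin_peak)
peak: 8.1 cells/5000 um^2 at -392 um from the front
```

i.e. 1719 of 1740 rendered cells are recovered, the curve is called
pattern 2, and its density peak of 8.1 cells/5000 μm² sits 392 μm on the
host side of the invasive front — close to the −400 μm at which the
generator centered the peak.

The same pipeline is available from the shell:

```sh
lqli simulate --pattern 2 --n 1 --seed 7 --out-dir sim/
lqli run --image sim/slide_0.tiff --front sim/front_0.geojson \
         --arc-position 520 --out-dir out/
lqli classify --profile out/profile_mean.csv
```

Every run writes its intermediates (detections, per-rectangle and mean
curves as CSV, ROI GeoJSON, pattern call JSON) plus a manifest with the
configuration hash and seed.

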