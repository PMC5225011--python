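# lumenwall

Bowel wall thickness is a key imaging biomarker of inflammation in Crohn's
disease, but measuring it by hand in MR colonography is slow and
observer-dependent. `lumenwall` automates the measurement on
contrast-enhanced T1 volumes, where the ingested contrast leaves the lumen
dark inside a bright, enhancing wall. It is aimed at imaging researchers
who want reproducible, densely sampled wall-thickness maps along a bowel
segment from a pair of seed points.

The pipeline, run per bowel segment:

1. **Particle-filter lumen tracking.** A cloud of states
   `x = (c, R, a, b, phi)` — centre, reference frame, elliptical
   cross-section — advances along the lumen. Each particle is weighted by
   `q ∝ exp(-W d)` where the cost `d` compares wall detections on radial
   rays (first intensity above a dynamically re-estimated lumen/wall
   threshold `k`) against the predicted ellipse. Weight degeneracy
   (effective sample size `1/Σq²` below 1% of the ensemble) terminates the
   track, which is what happens at a collapsed segment.
2. **Centreline extraction.** The particle history becomes a speed field
   `G(y) = Σ q_i exp(-‖y-x_i‖²/h²)`; fast marching solves the Eikonal
   equation `G|∇T| = 1` and steepest descent on `T` from the end point
   yields the fastest geodesic — a smooth centreline that stays inside the
   lumen, framed by rotation-minimising frames.
3. **MRF wall labelling.** On radial cross-sections every (frame, angle)
   site picks a radial distance label. Node potentials reward a strong,
   correctly oriented image gradient with no bright voxels crossed en
   route; edge potentials `e^{-γ|f_i-f_j|} e^{-λ(1-min/max)²}` tie
   neighbouring sites to similar distances and intensities; max-product
   belief propagation gives the inner contour, then the same machinery run
   outward along the contour normals gives the outer contour. Thickness is
   the inner-to-outer distance per site, and observer ROI points are
   matched to the nearest inner-wall point (failure beyond 5 mm).

A synthetic phantom generator (straight / torus / helix tubes with
partial-volume ramps, haustra, collapse, bias field, noise) provides
analytic ground truth for every stage.

## Worked example

Generate an 80 mm phantom with a 3 mm wall, track it, and measure:

```bash
lumenwall phantom --length 80 --thickness 3 --out ph.nii.gz \
    --truth-out gt.json --seed-spec-out seed.json
lumenwall track --volume ph.nii.gz --seed-spec seed.json \
    --particles 150 --out hist.csv
lumenwall centreline --volume ph.nii.gz --history hist.csv \
    --seed-spec seed.json --out cl.csv
lumenwall measure --volume ph.nii.gz --centreline cl.csv \
    --history hist.csv --out meas.csv
```

which reports

```
phantom written to ph.nii.gz (shape (35, 35, 115))
72 iterations, termination=end_reached
centreline 70.0 mm, 72 points
4608 measurements
```

— the tracker stepped 72 mm at 1 mm per iteration and stopped at the end
point; the measurement table holds one row per (frame, angle) site with
inner point, outer point and `thickness_mm`. On this phantom the mean
measured thickness is 3.25 mm against a true 3 mm: recovery is within one
0.25 mm radial label step, the quantisation of the wall model. Matching a
single observer ROI on the inner wall:

```bash
lumenwall evaluate --measurements meas.csv --roi roi.csv
```

```json
{
  "n_roi": 1,
  "n_matched": 1,
  "match_fraction": 1.0,
  "mean_difference_mm": 0.25,
  "sd_difference_mm": 0.0
}
```

`match_fraction` is the share of ROIs with a measurement within 5 mm;
differences are measured-minus-reference thickness, summarised with
Bland–Altman limits of agreement. The same pipeline runs end-to-end from a
YAML file (`lumenwall run --config cfg.yaml`), writing measurements,
centreline, particle history, and a JSON report with the ESS and threshold
traces, termination reason and versions; identical configuration and seed
reproduce byte-identical CSVs.

For patient data, the seed spec JSON takes a start point in the lumen, an
initial tangent, and either an ellipse or at least five inner-wall boundary
points (fitted by direct least squares), plus an end point roughly 10 cm
downstream — the file-based equivalent of seeding in a DICOM viewer.

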