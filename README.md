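# pensonar

Sonar-based quantification of fish avoidance behaviour in net pens.

When a point-source stimulus — a tone from an underwater speaker, a
submerged light — switches on at the centre of a sea cage, farmed fish
redistribute around it. A 360° mechanical scanning imaging sonar mounted on
the same structure sees the school as an annulus; how far its inner edge
sits from the structure, and how that distance changes from before to
during to after a 60-s stimulus, is a direct behavioural read-out of
avoidance (the school backs off), attraction (it closes in), or flight (it
leaves the instrumented volume entirely). `pensonar` implements that
read-out end to end for researchers studying stimulus–response behaviour of
penned fish:

* an agent-based simulator of annular fish schools with known ground-truth
  response dynamics, treatment schedules (60-s stimuli, 10-min breaks), and
  realistic sonar noise;
* circular-scan rendering and **Cumulative Fish Presence (CFP)** images:
  pixelwise-maximum accumulation of all revolutions inside trimmed 50-s
  phase windows;
* three-category segmentation (clear **pattern** / fish **out of range** /
  **invalid**) with a deterministic classical backend and an optional
  trainable backend, producing the binary fish-free region around the
  structure;
* the **avoidance distance**: the mean distance from the fish-free region's
  inner-perimeter pixels to the structure centre,

      d = (1/|C|) Σ_{p ∈ C} ‖p − c‖ · s,

  with C the traced contour, c the centre pixel and s the pixel scale,
  censored at max range for flight responses;
* a from-scratch **PERMANOVA** on the resulting distance tables: Euclidean
  distance, crossed fixed/random factors with expected-mean-squares
  denominators, permutation of reduced-model residuals (pseudo-F, 9999
  permutations by convention), parametric tail p-values for small
  permutation spaces, term pooling at the 25% level, and pairwise
  follow-ups.

See `docs/methods.md` for the models and numerical choices.

## Worked example

Simulate one trial whose school backs off by 28% during each of three 60-s
stimuli, and recover that effect through the full imaging chain:

```python
from pensonar import effect_recovery

res = effect_recovery(0.28, n_replicates=3, seed=1)
print(res.measurements.groupby("phase")["distance_m"].mean().round(3))
print(f"mean increase during vs before: {res.mean_percent_increase:+.2f}%")
```

```
phase
after     1.988
before    1.995
during    2.565
Name: distance_m, dtype: float64
mean increase during vs before: +28.61%
```

The before and after phases sit at the 2.0-m baseline (the school
re-aggregates once the stimulus stops), the during phase at the displaced
radius, and the during-vs-before contrast recovers the +28% ground truth to
within a percentage point.

The `analysis/` scripts run the same study as a file-based chain — simulate
two pens with different displacement factors (01), build CFP triplets (02),
segment and measure (03), run the mixed Timing × Pen PERMANOVA with pooling
and pairwise follow-ups (04), and summarise effect recovery and test
calibration (05):

```sh
python analysis/01_simulate_trials.py --seed 1
python analysis/02_build_cfp_images.py
python analysis/03_segment_and_measure.py
python analysis/04_permanova_stats.py
python analysis/05_effect_recovery.py
```

Tables land in `results/`, bulky rasters in `scratch/`. Step 04 prints the
characteristic signature of a genuine acute response — During > Before with
Before ≈ After — for each pen.

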