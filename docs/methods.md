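# Methods

`pensonar` quantifies how a school of farmed fish redistributes around a
point-source stimulus (a tone or a light) suspended at the centre of a sea
pen, using a 360° mechanical scanning imaging sonar co-located with the
stimulus. This note documents the models, the numerical choices, and what
the synthetic experiments do and do not establish.

## Observation model

A scanning sonar sweeps one beam through `n_bearings` bearings per
revolution (~8 s for a Ping360-class unit) and records `n_range_bins`
echo-strength samples per beam, `range_resolution` metres apart. One
revolution is a polar intensity array; painting each sample at
`(r cos θ, r sin θ)` onto a centred square raster gives the circular-scan
image on which all downstream imaging operates. Defaults: 400 bearings ×
200 bins × 0.05 m (10 m instrumented range), raster 401 × 401 px at
0.05 m/px. Overlapping samples combine by maximum — the raster encodes
presence, not energy, and is robust to the many-samples-per-pixel
degeneracy near the centre. Rounding to pixels is half-away-from-zero with
half-integer snapping, which makes quarter-turn bearing shifts exact raster
rotations; `np.rint`'s half-to-even rule does not.

## School model (synthetic data)

The generator assumes what the imaging method assumes: the school forms an
annulus centred on the structure. Each of `n_agents` (default 150) agents
holds an angular position advancing at `swim_angular_speed` (0.1 rad/s) and
resamples its radius every revolution as `r(t) + |N(0, σ)|` with half-normal
outward spread σ = 0.5 m: the *inner* perimeter stays crisp, the outer edge
diffuse, as the segmentation requires. The ground-truth inner radius
follows first-order response dynamics

    r(t) = r0                                   before onset
    r(t) → r0 (1 + δ)   with time constant τ    during exposure
    r(t) → r0           with the same τ         after offset

with r0 = 2.0 m and τ = 1 s by default; the decay tail is truncated to zero
at 5τ past the offset so the baseline holds exactly between events. δ > 0
is avoidance, δ < 0 attraction, and δ large enough to push the school past
the instrumented range (allowed only with `out_of_range_flag`) emulates a
flight response. τ is a free parameter of the generator, not an estimate of
fish behaviour — real recovery times are not identifiable from the windowed
design, which only requires recovery to be complete a few seconds after
offset.

Echoes are isotropic Gaussian blobs (σ = 2 range bins × 1 bearing bin) with
multiplicative lognormal speckle (CV 0.3), on top of exponential background
noise (mean 0.05 of the unit echo amplitude) and a bright ring artifact at
the exclusion radius standing in for the structure's own echo. These
acoustic parameters are chosen to make classical segmentation nontrivial
but solvable; they are not calibrated to any instrument.

Treatment schedules follow the field protocol: 60-s stimuli, 600-s breaks,
each level repeated a fixed number of times in seeded-random or sequential
order.

## Phase windows and CFP images

Each event is analysed over three 50-s windows — before, during, after —
obtained by trimming 5 s off both ends of each 60-s phase to avoid
treatment transitions. All revolutions lying *fully* inside a window are
rendered and accumulated pixelwise by maximum into one Cumulative Fish
Presence (CFP) image ("was a fish ever detected here"); partially included
revolutions are excluded because they would mix bearings recorded on either
side of a transition. Sum and mean reductions exist behind a switch but the
fish-free-region semantics assume the maximum.

## Segmentation

Every CFP image receives exactly one category:

* **pattern** — a clear annular distribution; the fish-free region is the
  star-shaped area `{r < ρ̂(θ)}` inside the school's inner perimeter;
* **out_of_range** — no echoes anywhere in the instrumented annulus
  (flight); the fish-free region is the full scan disc;
* **invalid** — saturated or unclear data; empty mask, no distance.

The default classical backend:

1. binarise at `echo_threshold` (default 0.5, half the nominal echo
   amplitude; an Otsu option exists but a data-driven threshold cannot
   distinguish a genuinely empty scan from a populated one, so the absolute
   default is what the flight category needs);
2. ignore everything inside the exclusion radius plus a 2-bin guard band
   (the structure's own echo);
3. drop isolated above-threshold pixels (fewer than 2 above-threshold
   neighbours in a 5 × 5 window). A single background stray near the centre
   is sampled by many adjacent bearings and would carve a wide false notch
   into the radial profile; real blobs always have company at any raster
   resolution, which is why this filter, unlike a component-area filter, is
   scale-consistent;
4. per bearing, take the nearest above-threshold radius ρ(θ) (max range if
   none); if fewer than `coverage_min` = 5% of bearings have any echo the
   category is out_of_range;
5. if the above-threshold fraction over the whole instrumented annulus
   exceeds `dense_fraction_max` = 0.25 the scan is saturated noise —
   invalid. No real school band fills a quarter of the annulus in these
   data; this global test is what separates "empty-ish profile because
   noise is everywhere" from "tight school hugging the structure";
6. smooth ρ(θ) with a circular moving median over 9 bearings; the fish-free
   candidate is `{r < ρ̂(θ)}`;
7. count above-threshold pixels strictly inside the candidate, eroded
   radially by 2 px to discount ordinary boundary roughness; a fraction
   above `noise_max` = 2% is invalid, otherwise pattern.

The trainable backend is a compact per-pixel classifier: each pixel of the
64 × 64-resized image is described by its intensity at four Gaussian scales
(normalised by a global intensity scale learned from the training set, so
absolute level still separates saturated from empty scans) plus its
normalised radius, and a small MLP maps features to a fish-free
probability. Thresholding at 0.5 gives the mask; the category is derived
from the mask itself — ≥ 98% of the (slightly shrunken) disc fish-free ⇒
out_of_range, ≤ 2% ⇒ invalid, else the connected component containing the
centre is the pattern region. It trains in seconds on synthetic labelled
data and exists to show the category/mask contracts are
backend-independent; it is not a reproduction of any particular deep
network. A manual-correction pathway (an override map from image id to
category) substitutes for interactive relabelling.

## Avoidance distance

The distance of one image is the mean Euclidean distance from the fish-free
region's inner-perimeter pixels to the structure centre, times the pixel
scale. The contour is the one-pixel-thick traced boundary: fish-free pixels
with at least one non-fish-free 4-neighbour (an 8-connected curve). Pixel
centres sit just inside the true boundary, so a perfect disc of radius R
reads about half a pixel low; no sub-pixel correction is applied.
out_of_range images are kept at `distance = max_range` with a `censored`
flag — dropping flights would discard exactly the strongest responses,
while capping them underestimates the effect, which is the conservative
direction; a sensitivity switch can exclude them. invalid images never
enter analysis tables.

## Permutational ANOVA

Distance-based sums of squares are partitioned over crossed factorial
designs (≤ 3 factors, fixed or random) by projecting the Gower-centred
squared-distance matrix onto orthonormal contrast subspaces; a term's SS is
the drop in residual SS when its columns join the model. With the Euclidean
distance on a univariate response — the only case in scope — this partition
is algebraically the classical ANOVA partition, an identity the test suite
verifies against statsmodels to 1e-8 and that the permutation engine
exploits by permuting response-space residuals rather than distance
matrices.

Pseudo-F denominators follow expected-mean-squares rules for crossed mixed
models: a fixed term crossed with a random factor is tested against that
interaction's mean square (e.g. Timing over Timing × Pen), all other terms
against the residual. Null distributions use Freedman–Lane permutation of
reduced-model residuals: for each tested term, residuals of the model
*without* that term are permuted and added back to the reduced fit, and the
full-model pseudo-F is recomputed. p-values include the observed statistic
in numerator and denominator, `p ∈ [1/(n_perm+1), 1]`. Permuted statistics
count as extreme at a relative tolerance of 1e-9 so algebraically tied
assignments (e.g. mirror labellings) are not lost to floating-point noise.
For small single-factor problems an exhaustive mode enumerates every
distinct assignment and reports the exact p without the +1 convention (the
observed assignment is part of the enumeration).

A parametric tail probability from the F(df1, df2) reference distribution
is always reported alongside and is the value consulted when fewer than 100
unique permutations exist; with Euclidean distance on a univariate Gaussian
response it is exact, so no moment-matched sampling is needed here. The
number of unique permutations is the multinomial coefficient
`n! / Π(cell size!)` over the tested term's cells.

Model pooling removes terms with permutation p ≥ 0.25, highest
interaction order first, refitting after each removal so the pooled SS and
df merge into the residual; a term marginal to a retained interaction is
never pooled. Pairwise follow-ups run the two-group test for every level
pair (t = √F), each pair seeded identically so a two-level factor's single
pair reproduces the omnibus test exactly.

## Pipeline, determinism, problem sizes

`run_pipeline` drives simulate → CFP → segment → measure → stats from one
seed and writes frames, images, masks, the tidy measurement CSV, stats
CSVs, a manifest (seed, config hash, version) and a log; a stage failure on
one event is logged and skipped, and a run with zero valid triplets is an
error. Identical config and seed give bit-identical measurement tables.

The bundled experiments run at deliberately desk-sized configurations: the
effect-recovery experiments use 3 replicate events per displacement factor
on the full-resolution geometry (≈ 270 revolutions per trial, seconds per
run); the calibration experiment uses 1000 null datasets of 3 × 10
observations with 999 permutations; fixtures and most unit tests use a
coarse 120 × 50-bin geometry. These sizes were chosen so the whole suite
runs interactively on one CPU while keeping every estimate's Monte-Carlo
error well inside its test tolerance.

## What the synthetic experiments show — and what they do not

Passing effect recovery shows the imaging chain is nearly unbiased for the
*ratio* of during/before distances under the generator's assumptions
(annular school, crisp inner edge, stationary baseline); the small residual
bias (≈ +0.5 percentage point) comes from inner-edge blob extent acting
equally on both phases. It does not validate the method against real sonar:
real recordings have beam-pattern artefacts, multipath, variable fish
target strength, and schools that are not perfectly annular, none of which
the generator emulates. The calibration experiment shows the permutation
test holds its nominal level for exchangeable Gaussian errors; it says
nothing about robustness to the censored (max-range-capped) distances a
flight-heavy dataset would produce.

## Known limitations

* Only one sonar stream is processed; no beam pattern, attenuation, or
  propagation physics.
* Univariate Euclidean responses only; no Bray–Curtis or other
  dissimilarities, no nested designs, no dispersion (PERMDISP-style) tests.
* The mixed-model EMS table covers at most one random factor, which is all
  the supported designs use.
* Sub-pixel contour refinement is out of scope; distances carry a ~half-
  pixel quantisation bias that cancels in phase ratios.
* Light-versus-depth contrasts are emulated only through the sign of δ; no
  light-field modelling.
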