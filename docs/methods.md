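# Methods

## The calibration problem

A dancing forager encodes the flight distance to a goal in the duration of
the waggle phase of each dance circuit. A feeder-training experiment
produces paired observations (feeder distance *d* in km, mean dance duration
*t* in s), and forage-mapping studies invert the fitted relationship to
decode distances from timed dances. The package treats three duration
components per dance — mean waggle phase *t<sub>w</sub>*, mean return phase
*t<sub>r</sub>* and their sum, the circuit duration *t<sub>c</sub>* — and
three candidate shapes for the distance–duration relationship. The analysis
unit is one dance per bee: per-dance phase timings are averaged
(*t<sub>w</sub>*, *t<sub>r</sub>* arithmetic means of the timed phases;
*t<sub>c</sub> = t<sub>w</sub> + t<sub>r</sub>* exactly), and a balanced
selection keeps each individually marked bee once so no single bee's
idiosyncratic tuning dominates the colony-level curve.

### One dance per bee, balanced across distances

When bees danced for several feeders, the selection keeps exactly one dance
per bee while equalising dances per feeder distance. A greedy pass assigns
bees (fewest candidate dances first) to their currently least-represented
distance, RNG breaking residual ties; a deterministic exchange pass then
shifts assignment chains from over- to under-represented distances until no
two connectable distances differ by more than one dance. The exchange pass
makes the final per-distance count variance minimal over all
one-dance-per-bee subsets (verified against brute-force enumeration in the
tests); the plain greedy alone can strand a distance one dance short.
Results are deterministic for a fixed seed, and the seed only matters when
genuine ties remain.

## Model families and fitting

* **Linear:** *t* = α + β·*d*, ordinary least squares.
* **von Frisch–Kratky (vfk):** *t* = *a* + (*b*/*c*)(1 − e<sup>−*c·d*</sup>);
  intercept *a* (s), initial slope *b* (s/km), flattening rate *c* (1/km),
  asymptote *a* + *b*/*c*. For fixed *c* the model is linear in (*a*, *b*)
  via the regressor (1 − e<sup>−*c·d*</sup>)/*c*, so fitting profiles *c*
  over a 200-point log-spaced grid on [10⁻³, 10] 1/km (configurable)
  followed by bounded scalar refinement. As *c* → 0 the curve degenerates to
  the line *a* + *b·d*; an optimum at a bound sets `boundary_warning_`.
* **Segmented:** *t* = β₀ + β₁*d* + β₂(*d* − ψ)₊, continuous at the
  break-point ψ by construction; second segment has intercept β₀ − β₂ψ and
  slope β₁ + β₂. ψ is profiled over a 400-point grid between the
  2nd-smallest and 2nd-largest distinct distance (configurable), then
  refined. A fitted ψ with fewer than two distinct distances on either
  (closed) side raises an unstable-break error.

Both profile searches are deterministic and free of starting-value
sensitivity; the grids are dense enough that the tests verify equality with
an exhaustive 10⁻⁴ km grid oracle on small datasets. Zero-RSS
(interpolating) fits are flagged `degenerate_` — their Gaussian likelihood
is unbounded — using a relative threshold of 10⁻²⁴·max(1, Σt²) to absorb
float noise.

### Model comparison

Fits of the same component are ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1),
with the profiled Gaussian log-likelihood ℓ = −(n/2)(log(2π·RSS/n) + 1).
Parameter counts include the residual variance: k = 3 (linear), 4 (vfk),
5 (segmented — the break-point is a fitted parameter). These are the
degrees of freedom conventional statistical environments report for these
model objects, and the package's AICc gaps are computed under them.

Two further diagnostics accompany the ranking:

* **Pearson r** between fitted and observed values, a goodness-of-fit
  summary comparable across families.
* **Bias flag**, a quantitative surrogate for inspecting residual plots:
  residuals are averaged per distinct feeder distance and the fit is
  flagged when (i) the sign sequence of those means, ordered by distance,
  has significantly too few runs (exact one-sided Wald–Wolfowitz runs test,
  level 0.05 — too few runs means long same-sign stretches, i.e. systematic
  lack of fit), or (ii) the mean residual at either extreme distance is
  both large (> 0.5 × overall residual SD) and statistically clear (> 2
  standard errors of that per-distance mean). The SE condition matters: with
  5–8 dances per distance the per-distance mean has an SE of ~0.4 residual
  SDs, and a bare 0.5·SD rule would flag the *true* model ~40% of the time;
  with it, simulated false-alarm rates are near zero while a line forced
  through a saturating truth is still flagged in the large majority of
  replicates. All three thresholds are exposed as arguments.

## Decoding

Inversion is closed-form per family: *d* = (*t* − α)/β (linear);
*d* = −ln(1 − *c*(*t* − *a*)/*b*)/*c*, defined for *a* < *t* < *a* + *b*/*c*
(vfk); piecewise-linear inversion choosing the segment whose duration range
contains *t* (segmented). Durations below the curve value at *d* = 0, or at
and above a saturating asymptote, raise out-of-range errors — the latter
names the asymptote, since it signals that an extrapolating piece is needed.

A `PiecewiseCalibration` chains model pieces over contiguous distance
intervals covering [0, ∞), validating continuity at the joints and strict
monotonicity over a scan grid. `build_study_calibration` uses the
saturating fit up to the training limit (default 1.7 km) and the second
segment of the companion break-point fit beyond it. Because the exact
anchoring of such an extrapolation is a free choice, the default shifts the
line vertically to equal the saturating curve at the switch distance
(recorded as `offset_s`); `anchor=False` reuses the segment unshifted,
accepting a small jump. Two published long-range calibrations for
*A. m. carnica* are bundled with parameters exactly as printed: a piecewise
waggle-duration curve (saturating to 1.4 km, linear beyond; continuous at
the joint to <10⁻³ s) and a linear circuit-duration extrapolation.

### Uncertainty

Decode intervals come from case resampling: the training dances are
resampled with replacement, the calibration's families are refit and the
duration re-inverted (default 1000 replicates, seeded). Case resampling was
chosen over residual resampling because dance-level noise grows with
distance and residual resampling would homogenise it. The interval is the
**expanded percentile** interval: end-points taken at tail levels
Φ(−√(n/(n−1))·t<sub>n−1,(1+γ)/2</sub>) instead of (1−γ)/2. In coverage
simulations at the study's sample size the plain percentile interval ran
~7% too narrow (91–92% coverage at nominal 95%); the t-adjusted levels are
the standard small-sample correction for this and bring measured coverage
to ~92–95% depending on seed. Decoded points beyond the maximum training
distance carry an `extrapolated` flag.

## Synthetic data

The generator emulates the long-range feeder-training design: nine feeder
distances 0.1–1.7 km in 0.2 km steps; 5–8 dances per distance (uniform);
total bee turnover (each dance by a fresh bee, with an option for bees to
revisit the next feeder so the balanced selection has work to do); four
waggle and four return phases per dance. Dance-level means follow a chosen
true curve — defaults are the fitted colony-level curves: saturating
(a = 0.1993 s, b = 2.0018 s/km, c = 0.6717 1/km) for waggle, linear
(1.3712 + 0.5238·d) for return — plus Gaussian noise truncated at zero.
The waggle SD interpolates linearly from 0.10 s at 0.1 km to 0.19 s at
1.7 km (only the endpoint dispersions are reported, so interpolation is the
least-assumption choice); the return SD is 0.31 s (midpoint of the reported
endpoint values 0.33 and 0.29 s). Phase-to-phase jitter within a dance uses
SD 0.05 s — a placeholder, as within-dance variability is not reported —
and an option rounds timings to 0.02 s to mimic 50 Hz video frames.
Quantization is generator-side only; ingest never rounds.

The **heterogeneity scenario** probes a colony-level confound: every bee is
strictly linear, but a bee assigned to the *i*-th of K distances gets slope
s₀(1 − γ·i/(K−1)), so close-foraging bees are steeper. With γ = 0.4 the
pooled colony data are concave although no individual is, and the segmented
model beats the line (by AICc) in ~90% of replicates — a reminder that
colony-level curvature does not by itself establish individual-level
non-linearity.

What the generator does *not* emulate: real per-bee repeatability across
distances, resource-quality effects on the return phase, temporal drift
over a training day, non-Gaussian heavy tails in timing errors, and
reader/measurement bias. Passing simulation tests therefore demonstrate
that the estimators recover the assumed generating structure at realistic
noise and sample sizes — not that field data satisfy those assumptions.

## Problem sizes and seeds

Simulation studies use sizes chosen to give stable Monte-Carlo estimates
while keeping the whole suite quick: 200 replicates for break-point
recovery (median |ψ̂ − ψ| ≈ 0.10 km at the study design, against the
0.15 km acceptance bound), 500 replicates × 400 bootstrap draws for decode
coverage, 100 replicates for the heterogeneity scenario, 1000 random
datasets for the RSS-nesting property. All stochastic components take
explicit integer seeds (NumPy `default_rng`); identical seeds reproduce
byte-identical datasets and decisions.

## Known limitations

* The AICc parameter-count convention (k = 5 counts the break-point) is a
  modelling choice; environments that treat ψ as fixed would shift the
  segmented model's AICc by roughly 2·(1 + small-sample term).
* The vfk linear limit is approached, not attained: at the default lower
  bound c = 10⁻³ the profiled RSS can exceed the OLS RSS by ~10⁻³
  relative for convex-leaning data. Supplying a smaller lower bound (e.g.
  10⁻⁸) makes the nesting inequality sharp.
* Bootstrap intervals reflect calibration uncertainty only; they do not
  propagate the measurement noise of the *decoded* dance itself.
* The segmented second slope can come out non-positive on noisy or
  short-range data, in which case building an extrapolating calibration
  from it correctly fails rather than producing a non-invertible curve.
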