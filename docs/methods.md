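# Methods

## Model and assumptions

The package models one-dimensional harmonic movement
`u(t) = a sin(ωt + ψ)` with the starting phase ψ drawn uniformly on
[−π, π) per recording.  All distributional results are phase-marginal: the
position of a rigid-mounted sensor sampled at an arbitrary time follows
the arcsine law on [−a, a], independent of ω and of the sampling instant.
Internally every distribution works in amplitude-normalised units
(a = 1); the amplitude enters only when trajectories are synthesised.

A fabric-mounted sensor is modelled as the rigid position plus an
independent bounded offset, `Y = U + Δ` with `Δ ~ U(−zL, zL)`.  The
assumptions behind this choice are deliberately minimal:

- the fabric is inextensible, so the offset can never exceed the fabric
  length `L` (here a fraction of the amplitude, `0 < L ≤ 1`);
- faster movement excites the fabric more, modelled by the saturating
  excitation factor `z(ω) = 1 − exp(−ω²) ∈ [0, 1)`, which keeps the
  offset inside ±L at any frequency;
- lacking further prior information, the offset is uniform within its
  range, and (in the simulator) independent from sample to sample.

No fabric physics (mass, stiffness, geometry, air drag) is represented;
`L` is the only material parameter.

## Closed forms

The fabric CDF is the convolution of the arcsine law with the uniform
kernel:

    F_Y(y) = (1 / 2zL) ∫_{y−zL}^{y+zL} F_U(v) dv
           = (G(y + zL) − G(y − zL)) / (2zL),

where `G` is the closed-form antiderivative of the arcsine CDF
(`G(v) = (v asin v + √(1−v²))/π + v/2` on |v| < 1, clamped to 0 / v
outside).  This single expression covers the whole parameter range,
including the degenerate case `zL = 1` where the flat middle region of the
piecewise form collapses to the single point y = 0.  The published
piecewise variant of the same result contains typesetting corruption in
that degenerate case; the antiderivative form is validated against an
independent adaptive-quadrature oracle (`fabric_cdf_oracle`) to ≤1e−6 on
dense grids in the test suite, which is the authoritative check.  The
density is the exact derivative `(F_U(y+zL) − F_U(y−zL))/(2zL)`.

## KS separability: supremum vs edge formula

`ks_distance_fabric` reports the Kolmogorov–Smirnov distance between the
fabric marginals of two frequencies, `sup_y |F_{Y1}(y) − F_{Y2}(y)|`.
Two evaluations are offered:

- `method="sup"` (default): the true supremum, located numerically on the
  closed-form CDF difference (4001-point grid bracket + bounded scalar
  refinement to xatol 1e−12; the support edge of the slower class is kept
  as an explicit extra candidate).  Because the difference of two smooth
  CDFs peaks where the densities cross, the maximiser lies strictly inside
  the support.
- `method="edge"`: the closed-form CDF gap at `y = 1 + z₁L`, the upper
  support edge of the slower class, where the slower CDF has already
  reached 1:

      D_edge = (−πw + 2w asin w + 2√(1−w²)) / (4π z₂ L),  w = 1 − (z₂−z₁)L.

  This quantity is sometimes quoted as the KS distance itself, but it is
  only a lower bound: for ω = 1 vs 2 rad/s at L = 1 the edge gap is 0.0322
  while the true supremum is 0.0434.  Empirical two-sample KS statistics on
  simulated data converge to the supremum, not the edge value, which is why
  the supremum is the default.  `ks_distance_derivative_L` is the exact
  L-derivative of the edge form,

      dD/dL = (π − 2(asin w + √(1−w²))) / (4π z₂ L²) > 0,

  confirming analytically that looser fabric always increases separation;
  the same monotonicity holds numerically for the supremum and is asserted
  on a grid in the tests.

## Simulator

`generate_dataset` draws `n_per_class` trajectories per class (class 0 at
ω_low, class 1 at ω_high), each `K = round(duration · fs)` samples on a
regular grid starting at t = 0 — with the defaults (duration 2π s, 10 Hz)
K = 63.  Per trajectory: one fresh phase; per fabric length, one fresh
i.i.d. uniform offset sequence.  Defaults mirror the simulated scotch-yoke
study: 200 trajectories per class, 1 vs 2 rad/s, amplitude 1, fabric
lengths 1/3, 2/3, 1 (sensors F1–F3) plus the rigid channel R1.  Seeding
uses one `SeedSequence` spawned into per-trajectory streams, so datasets
are bitwise reproducible and trajectories mutually independent.

The white-noise offset is a modelling choice, not a physical claim: only
the marginal of Δ is specified by the model.  An optional moving-average
smoothing length is available for qualitatively fabric-like (correlated)
jitter but is off in every shipped protocol.  Consequences of whiteness:
simulated fabric windows are "noisier than real fabric" at short lags, so
multi-sample-window results quantify the model, not any particular
textile.  What passing tests show is that the *mechanism* — marginal
widening creating KS separation that a classifier can exploit — behaves as
derived; they cannot show that a specific garment realises these numbers.

## Evaluation protocol

Windows of `i = max(1, round(window_s · fs))` consecutive samples are taken
with stride 1 (`K − i + 1` per trajectory), inheriting the trajectory
label.  One-sample windows are deliberately allowed: they are the regime
where the marginal-distribution mechanism acts alone (and correspond to
the 0.025 s windows of 40 Hz hardware).  At two or more samples a rigid
sensor already encodes frequency through the deterministic lag structure
of the sinusoid, which is why the rigid-vs-fabric ordering is a
short-window phenomenon.

Train/test splitting is at the trajectory level, stratified by class
(default 50/50), so overlapping windows never leak across the boundary —
possibly stricter than window-level splitting.  Standardisation is a
single scalar mean/std over all training-window entries (positions share
one physical unit), applied to both sides; it is on by default in every
protocol.  The classifier is a libsvm RBF-kernel SVM (scikit-learn `SVC`)
with C = 1 and the `gamma='scale'` width rule `1/(i · var)`; both are
exposed in `ClassifierConfig`.  Accuracy is window-level (each window
predicted independently, "online" style); a trajectory-majority vote can
be built from the per-window predictions but is not the reported metric.
The empirical KS statistic of a trial is the two-sample statistic between
the pooled test-set position samples of the two classes.

Sweeps re-simulate a fresh dataset every trial by default (fresh phases
and offsets; `resimulate=False` gives the split-only variant) and report
mean ± sd over trials.  The frequency sweep includes the analytic KS
prediction per condition and the Pearson correlation between D and mean
accuracy across conditions.

## Numerical and design choices

- Samples per trajectory: `K = round(duration · fs)`; durations that give
  fewer than 2 samples are rejected.
- `ks_distance_fabric` requires the lower frequency first, returns 0 for
  equal frequencies, and raises if the order is reversed.
- Degenerate z-score (constant training signal) passes through unchanged
  with a warning rather than dividing by zero.
- Gap filling uses scipy's `CubicSpline` through the retained samples;
  retained values are untouched, leading/trailing missing values are
  trimmed with a warning, and fewer than 4 valid points is an error.  CSV
  ingestion validates column presence, numeric content (with row numbers
  in messages), per-channel constant sampling interval to 1%, and label
  constancy per trajectory.
- Problem sizes in the shipped test protocols are scaled for quick,
  repeated runs: the asymptotic-accuracy check uses the full 200
  trajectories per class over 20 repeats, while the short-window ordering
  check uses 50 per class over 50 repeats — the ordering is a marginal
  property and is stable at that size.  The window grid spans 0.1 s (one
  sample) to the full trajectory (6.3 s), where accuracy saturates at
  100%.

## Known limitations

- One-dimensional movement, binary classes, frequency as the only class
  difference.  No wind/offset bias in Δ, no multidimensional extension.
- The uniform, white offset understates temporal correlation of real
  fabric motion; empirical KS values on real recordings may differ from
  the analytic prediction even when the mechanism holds.
- The SVM hyperparameters are fixed defaults, not tuned per condition;
  absolute accuracies (not orderings) shift with C and γ.
- Analytic KS values assume the uniform-offset model is exact; for
  ingested external data only the empirical statistic is meaningful.
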