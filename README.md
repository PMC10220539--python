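# loosewear

Probabilistic modelling of motion sensors mounted on **loose clothing**, and
of the counterintuitive finding that such sensors can recognise activities
*better* than sensors strapped rigidly to the body — especially when the
classifier must decide from very short time windows.

The package is for researchers in wearable sensing and human activity
recognition (AR) who want to understand, predict or reproduce this effect
with a fully synthetic, seeded pipeline: closed-form position
distributions, analytic Kolmogorov–Smirnov (KS) separability, a stochastic
scotch-yoke simulator, and a windowed SVM evaluation protocol.

## The model

A point on a rigid body driven by a scotch yoke moves as

$$u(t) = a\sin(\omega t + \psi), \qquad \psi \sim \mathcal U[-\pi, \pi),$$

so its position marginal is the **arcsine law** (a Beta(½, ½) shape on
$[-a, a]$), with CDF $F_U(u) = \arcsin(u)/\pi + 1/2$ for $a = 1$.
Crucially, $F_U$ does not depend on $\omega$: two movements that differ
only in frequency are *statistically indistinguishable* from rigid-sensor
positions, $D(U_{\omega_1}, U_{\omega_2}) = 0$ for the KS distance $D$.

A sensor on an inextensible fabric strip of length $L \le a$ sees the same
motion plus a bounded random offset,

$$Y = U + \Delta, \qquad \Delta \sim \mathcal U(-zL,\; zL), \qquad
z = 1 - e^{-\omega^2},$$

where the excitation factor $z$ captures that faster movement shakes the
fabric harder (saturating at $z \to 1$).  The marginal of $Y$ is the
convolution of the arcsine law with a uniform kernel and has an exact
closed-form CDF.  Because the half-width $zL$ grows with $\omega$, the two
classes now have *different* marginals:
$D(Y_{\omega_1}, Y_{\omega_2}) > 0$, and the distance increases
monotonically with the fabric length $L$ — the looser the garment, the more
separable the movements.  The package evaluates this distance both as the
true supremum of the CDF difference and as the analytic expression for the
CDF gap at the support edge $y = 1 + z_1 L$ (a closed-form lower bound;
see `docs/methods.md`).

The link to recognition accuracy is made operational with the standard AR
protocol: trajectories are cut into all overlapping windows of $i$ samples
(stride 1), z-scored with training statistics, and classified with an
RBF-kernel SVM.  At one-sample windows the classifier sees only the
marginals, so rigid sensors sit at chance while fabric sensors benefit
from their KS separation; at long windows every sensor converges to 100%.

## Worked example

```python
from loosewear import (DatasetSpec, ActivityRecognition, generate_dataset,
                       ks_distance_fabric, ks_distance_rigid)

dataset = generate_dataset(DatasetSpec(n_per_class=100, seed=42))

ks_distance_rigid(1.0, 2.0)        # 0.0     — rigid sensors are blind
ks_distance_fabric(1.0, 2.0, 1.0)  # 0.043357
ks_distance_fabric(1.0, 2.0, 1/3)  # 0.024192 — tighter fabric, less separation

res = ActivityRecognition(dataset, "F3", window_s=0.1).fit(n_trials=5, seed=0)
print(res.summary())
```

```
Activity recognition results
============================
sensor:           F3
window:           1 samples (0.1 s)
trials:           5
accuracy:         0.5497 +/- 0.0046
empirical KS D:   0.0465
analytic KS D:    0.0434
condition:        omega 1.0 vs 2.0 rad/s, fs 10.0 Hz, 100 trajectories/class
```

The loosest fabric sensor (`F3`, $L = 1$) scores 55% from single-sample
windows — modest, but systematically above chance, and its empirical KS
statistic (0.047) agrees with the analytic prediction (0.043).  The same
model on the rigid channel `R1` gives accuracy 0.4998 ± 0.0004 and analytic
$D = 0$: pure chance, exactly as the model predicts.

## Command line

```bash
loosewear simulate --n-per-class 200 --seed 1 --out data/
loosewear ks --omega1 1 --omega2 2 --L 1
loosewear sweep-window  --n-per-class 50 --repeats 20 -w 0.1 -w 0.5 -w 2.5 --out run/
loosewear sweep-frequency --repeats 20 --out run2/
loosewear compare-paired --csv pairs.csv
```

Every command records the fully resolved configuration and seed in a
`run_config.json` next to its outputs.  Externally recorded data can be
analysed through the same pipeline if supplied as a CSV with columns
`trajectory_id, sensor_id, time_s, position, class_label` (one row per
sample per sensor; missing samples may be blank and are repaired by cubic
spline interpolation).

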