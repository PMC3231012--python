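# Methods

## Problem setting

A steady-state electronic-nose measurement is a vector of `m` sensor
responses (dimensionless sensor units). For a universe of `n` pure compounds
— the canonical fixture is (M, E, A) = methanol, ethanol, acetone with
`m = 8` features obtained by averaging 32 replicate carbon-black channels in
groups of 4 — the package answers two questions: which non-empty subset of
components a sample contains (classification over the `2^n − 1` component
sets), and at what concentration each component is present (estimation, in
ppm).

Both rest on two physical assumptions about composite polymer sensors:

* **homogeneity** — a sensor's response to a pure compound is proportional
  to its concentration, `r_i(c_j) = α_ij c_j`;
* **linear additivity** — a mixture's response is approximately the sum of
  its components' responses.

Homogeneity implies that the *normalized* pattern of a pure compound is
concentration-invariant, which is what makes component-set classification
meaningful on normalized data.

## LWNN classification

Each class is summarized by its centroid (coordinate-wise mean) and a
positive weight vector used in a weighted Euclidean distance. The weights
solve

```
min_ω  Σ_p∈class Σ_j ω_j (p_j − o_j)²   s.t.   Π_j ω_j = 1,
```

whose Lagrangian solution is `ω_j = λ / S_j`, `S_j = Σ_p (p_j − o_j)²`,
`λ = (Π_j S_j)^(1/m)`. Only the geometric-mean normalizer satisfies the
unit-product constraint, and it is what the implementation uses; the
constraint is verified to 1e-9 in the tests. Classification takes the
argmin of the weighted distance; the square root is kept for fidelity to
the distance definition even though it does not affect the argmin.

Numerical choices:

* **Scatter floor.** `S_j` is clamped below at `1e-12 × mean(S)` before
  inversion so a feature that is constant within a class cannot receive an
  infinite weight. A class with *all-zero* scatter (e.g. a singleton) gets
  unit weights — it carries no anisotropy information.
* **Tie-break.** Equidistant centroids resolve to the lexicographically
  smallest canonical label, making classification deterministic.
* **Preprocessing.** LWNN consumes l2-normalized patterns by default (the
  distance is Euclidean-based; the normalization mode is configurable,
  including none). Replicate averaging always precedes normalization. The
  WCLS estimator, by contrast, consumes raw averaged responses, because its
  models relate absolute response magnitudes to concentration.

## Concentration estimation

Stage 1 fits through-origin slopes `α_ij` per sensor/component by least
squares over the samples containing only component `j` (`α = Σ r c / Σ c²`).
Stage 2 fits, per sensor, an ordinary least-squares regression of the
observed response on the regressors `{α_ij c_j}_j` plus an intercept,
yielding `β_i,offset` and `β_ij`; the composed gain matrix `G_ij = β_ij α_ij`
is stored explicitly. By default all training samples (pure and mixed)
enter the β fit; a switch restricts it to mixtures only. Rank-deficient
designs are reported per sensor rather than silently pseudo-inverted.

Given observed responses `t`, CLS solves `min_{c≥0} ½‖G c − (t − β_offset)‖²`
with an active-set non-negative least-squares solver (deterministic at these
sizes, `n ≤ ~6`, `m ≤ ~32`); the intercepts are subtracted, not constrained.
WCLS scales row `i` of the system by `√ω_i` first, with the sensor
reliability weights

```
ω_i = λ / R_i,   R_i = Σ_k (r_i(c^(k)) − t_i^(k))²,   λ = (Π_i R_i)^(1/m)
```

computed over the same training set used to fit the models (configurable to
mixtures only). `R_i` is floored at `1e-12 × mean(R)` exactly like the LWNN
scatter, so a perfectly fitted sensor cannot acquire infinite weight. With
unit weights WCLS reduces bit-for-bit to CLS.

## Synthetic bench data

The generator emulates the reference measurement campaign the package's
fixtures mirror: `n = 3`, `m = 8`, 133 samples split 67 train / 66 test by a
seeded permutation. Defaults, chosen once as bench-realistic:

* **Slopes** log-uniform on (0.1, 1.0) response-units/ppm, giving signals of
  roughly 3–100 units over the 28–85 ppm concentration range.
* **Collinearity.** Methanol and ethanol evoke nearly the same pattern in
  carbon-black arrays, so the preset blends the ethanol column as
  `0.95·α_M + 0.05·α_E` with 2 % multiplicative jitter (cosine similarity
  > 0.99). This is the main difficulty driver for both tasks.
* **Noise** additive Gaussian, SD 0.5 response units per sensor (a few
  percent of a typical mixture signal); per-sensor SD vectors supported for
  heteroscedastic studies.
* **Design.** Pure samples at {28, 45, 57, 68, 85} ppm for methanol and
  {28, 45, 56, 68, 85} for ethanol/acetone; two- and three-component
  mixtures on the full {34, 51, 68} ppm grid. The 69 distinct design points
  are replicated twice and truncated to 133 measurements.
* **Mixing modes.** Additive is the reference. The departures are minimal
  one-parameter transforms of the summed pure signals: *masking* attenuates
  every non-dominant component's contribution by `(1 − s)`; *hypoadditivity*
  scales a k-component mixture's sum by `(1+s)^−(k−1)`; *synergy* by
  `(1+s)^(k−1)`. At zero noise and equal strength, hypoadditive ≤ additive ≤
  synergistic holds elementwise, and pure samples are identical across
  modes.

What the generator does **not** emulate: sensor drift, transient response
kinetics, temperature/humidity effects, saturation at high concentration,
and instrument-specific baselines. Passing tests on synthetic data therefore
demonstrate the correctness and qualitative behaviour of the algorithms, not
the accuracy figures any particular instrument would achieve.

## Behaviour the simulations establish

* **Noise-free identifiability.** With additive noise-free data the full
  pipeline (pure fit → mixture fit → weights → WCLS) recovers every test
  concentration to < 1e-6 ppm.
* **Weighting benefit.** With 2 of 8 sensors at 5× noise SD, the learned
  weights suppress the noisy sensors (ω ≈ 0.1) and WCLS mean RMSE drops well
  below CLS — the scenario sensor weighting exists for.
* **Pure-vs-mixture degradation.** On strictly additive synthetic data a
  *well-specified* estimator is, if anything, *better* on pure samples: the
  non-negativity constraint truncates errors along the ill-conditioned
  methanol–ethanol direction, while interior (mixture) solutions absorb the
  full noise amplification. The degradation of pure-sample estimates
  relative to full mixtures that is observed on real bench data is a
  *misspecification* effect of non-additive odor mixing. The package's
  collinearity study therefore runs the bench preset with hypoadditive
  mixing (strength 0.3) at high signal-to-noise (SD 0.1): one set of affine
  β coefficients cannot fit pure, two- and three-component regimes at once,
  the compromise lands nearest the (more numerous) mixtures, and pure-sample
  RMSE (≈ 9–14 ppm) then exceeds three-component RMSE (≈ 5–8 ppm) —
  reproducing the qualitative pattern and magnitudes of the published
  reference tables, where the worst three-component RMSE is 5.34 ppm while
  pure samples reach ~20 ppm.
* **Classification.** LWNN is evaluated once (K = 1 by construction) against
  KNN baselines swept over K = 1..5; on the bench preset its accuracy is
  comparable to the best KNN and it benefits from per-class anisotropy.

## Baselines and reporting conventions

PCA projects onto the top principal directions (default: smallest dimension
capturing ≥ 95 % of training variance). The LDA projection solves the
generalized eigenproblem `S_b v = μ (S_w + εI) v` with
`ε = 1e-8 × trace(S_w)/m`, default dimension `min(N − 1, m)`; the ridge
keeps singleton classes from making `S_w` singular. KNN ties are resolved
deterministically: distance ties keep sample order, vote ties prefer the
label seen nearest, then the lexicographically smallest label (a rule is
mandatory for even K). Accuracies and RMSEs are reported to 2 decimals; an
RMSE is always computed over all `n` components, counting absent components
at 0 ppm.

## Problem sizes

The default test suite and the acceptance script run on the 133-sample bench
preset (3–5 seeds per study), 1000 random weight instances, and 300–500
random solver instances with `n ≤ 6` (so the `2^n` enumeration oracle stays
exact); the full acceptance run completes in a few seconds.

## Known limitations

Concentrations are in ppm throughout; no unit conversions. The estimator
assumes the affine additive model — masking, hypoadditivity and synergy in
the data are stressors it is *not* corrected for. LWNN cannot estimate
concentrations, and its class count grows as `2^n − 1` with the number of
components. The CSV format carries steady-state scalar responses only, not
transient traces.
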