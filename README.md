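# popdemix

Population-level analysis of reach-to-grasp neural recordings from macaque
medial posterior parietal cortex (area V6A), built around **demixed
principal component analysis (dPCA)**.  Neurons in this area mix several
task variables in their firing; dPCA compresses the trial-averaged
population activity like PCA while assigning each component to a single
task-variable *marginalization*, so one can ask how much population
variance encodes the task parameter (target position, wrist orientation or
grip type), the visual condition (movement in light vs in dark), their
interaction, or nothing but trial time.

The package is aimed at systems/computational neuroscientists who want a
tested, reusable version of this pipeline: the decomposition itself, the
variance-split statistics, time-resolved decoding from the demixed axes,
and discrimination-distance time-courses — plus a synthetic
pseudo-population generator with *planted*, analytically known variance
structure, so every stage has a recovery oracle.

## The method

Trials are binned at 40 ms from −4500 to +2500 ms around movement onset and
averaged per condition into a tensor `X` of shape `N × S × V × T` (neurons ×
parameter levels × visual conditions × time bins).  After per-neuron
centering, `X` splits exactly into four ANOVA-style parts

```
X = X_ci + X_param + X_vis + X_int
```

(condition-independent, parameter, visual, interaction).  For each part
`X_φ`, dPCA finds decoder rows `D_φ` and unit-norm encoder columns `F_φ`
minimizing the reduced-rank ridge loss

```
L = Σ_φ ‖X_φ − F_φ D_φ X‖² + λ‖F_φ D_φ‖²
```

via the closed form `A_φ = X_φ Xᵀ (X Xᵀ + λI)⁻¹` followed by SVD truncation
of `A_φ X`.  Unlike PCA (`D = Fᵀ`), the decoding axes are not constrained
to be mutually orthogonal — that freedom is what demixes the components.
Downstream procedures: percentage variance per marginalization (with
chi-squared comparisons of percentages), stratified Monte-Carlo
leave-group-out cross-validated decoding using the leading decoding axis as
a linear classifier (shuffle null, ≥10-consecutive-bin significance runs),
and per-bin euclidean distances between level-averaged component
projections with neuron-bootstrap CIs and a factor-exchange randomization
test.

## Worked example

Generate a reach-style pseudo-population (3 targets × 2 visual conditions,
149 neurons, 7–15 Poisson-noise trials per condition) with planted variance
shares, fit dPCA, and compare shares:

```python
import popdemix as pdx

design = pdx.reach_design()                      # 3 × 2 design, 175 bins
spec = pdx.EffectSpec(
    target_fractions={"condition_independent": 0.58, "parameter": 0.24,
                      "visual": 0.11, "interaction": 0.07},
    noise_model="poisson", baseline_hz=400.0, signal_std_hz=140.0,
    trials_per_condition=(7, 15), seed=11)
rec = pdx.generate_population(design, 149, spec)
tensor = pdx.build_rate_tensor(rec)
result = pdx.fit_dpca(tensor, q_per_marginalization=10)
for label, pct in sorted(result.variance_split.items(), key=lambda kv: -kv[1]):
    print(f"{label:22s} {pct:5.1f}")
```

prints

```
condition_independent   55.5
parameter               24.5
visual                  11.5
interaction              8.5
```

— the planted 58/24/11/7 % split, recovered from noisy trials to within a
few points (the residual tilt is Poisson noise energy spreading across
marginalizations; see `docs/methods.md`).  Cumulative variance at 15
components was dPCA 95.6 % vs PCA 95.8 %: demixing costs almost no
compression.  A chi-squared comparison of the rounded parameter and visual
shares (24 % vs 11 % out of 100 count points each) gives
`chi2 = 6.64, p = 0.010`: the parameter share is significantly larger.

The same objects drive decoding and distance analyses:

```python
res = pdx.decode_timecourse(rec, target="parameter", n_iterations=25, seed=4)
res = pdx.significance_intervals(rec, res, n_shuffles=25)
bands = pdx.bootstrap_bands(rec, parameter_levels=("left", "right"), n_bootstrap=50, seed=2)
```

A `popdemix` CLI wraps the same functions
(`simulate`, `dpca`, `decode`, `distance`, `compare-variance`, `run`).

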