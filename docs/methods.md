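# Methods

## Data model

The unit of analysis is a *pseudo-population*: `N` neurons recorded
separately under a common factorial design of `S` task-parameter levels
(3 reach targets, 2 wrist orientations, or 5 grip types) × `V = 2` visual
conditions (light/dark).  Firing rates are binned at 40 ms on a fixed
peri-event grid; the default window is −4500…+2500 ms around movement
onset (175 bins).  Bins are half-open, `[start + t·40, start + (t+1)·40)`
ms, 0-based internally with ms labels in outputs.  The grip-type design
concatenates two epochs aligned on object illumination and on movement
onset; the exact per-epoch extents are an analysis choice, and the factory
uses −1000…+1600 ms and −1600…+2400 ms (65 + 100 bins) with an
explicit boundary index.  Interval logic (decoding significance runs,
distance separations) never crosses the boundary, since the concatenated
time axis is discontinuous there.

Per-condition trial counts may vary (7–15 by default); missing trial slots
are represented by an explicit mask and never imputed.  Trial averaging
produces the PSTH tensor `X (N × S × V × T)`; per-neuron centering removes
the grand mean over `(S, V, T)` with *equal condition weights* regardless
of trial counts, so unbalanced designs do not bias neuron means.

## Marginalization

Centering makes the factorial split exact:

- condition-independent: mean over `(s, v)` at each `(n, t)`;
- parameter: mean over `v` minus the condition-independent part;
- visual: mean over `s` minus the condition-independent part;
- interaction: the remainder.

These are orthogonal projections; the parts sum to the centered tensor to
machine precision and each part averages to zero over the factors it does
not depend on.  The *signal-variance split* is
`‖X_φ‖² / Σ_ψ ‖X_ψ‖²` — raw shares of the centered PSTH tensor, with no
noise-floor correction (raw shares are the transparent default; the noise-inflation this
implies is quantified below).

## Demixed PCA

Per marginalization φ the loss
`‖X_φ − F_φ D_φ X‖² + λ‖F_φ D_φ‖²` is minimized over rank-`q_φ` maps by
the reduced-rank ridge solution: `A_φ = X_φ Xᵀ(X Xᵀ + λI)⁻¹`, SVD-truncate
`A_φ X`, take the top left singular vectors as encoder columns `F_φ` and
`D_φ = F_φᵀ A_φ`.  The classic two-term (stimulus/time) presentation of the loss
generalizes to one term per marginalization, matching the four-way
variance split reported above.  Numerical choices:

- `λ` defaults to `1e-6 · ‖X‖² / size`, a pure numerical stabilizer; an
  exact `λ = 0` fit is available, and `(X Xᵀ + λI)` is inverted by a
  hermitian pseudo-inverse so exactly low-rank (noiseless synthetic) data
  still yields the minimum-norm solution.  `λ = 0` with `N > S·V·T` is
  refused with a message instructing `λ > 0`.
- 10 components per marginalization are kept by default.
- component variance is `‖d_i X‖²` (encoders are unit-norm); components
  are ordered globally by it.  Cumulative variance is
  `1 − ‖X − F_{1:q} D_{1:q} X‖²/‖X‖²`; because each partial reconstruction
  has rank ≤ q, it can never exceed the PCA curve.
- signs are arbitrary; each component is flipped so the time-averaged
  projection of the first condition is ≥ 0, keeping outputs deterministic.

When only one marginalization carries variance and `λ = 0`, the solution
collapses to ordinary PCA (`D = Fᵀ`); this limit is tested to 1e-6.

## Synthetic populations with planted structure

Each neuron's noiseless rate is
`baseline + Σ_φ Σ_k w_{nφk} · g_{φk}(s, v, t)`, where each latent `g`
lies entirely in one marginalization (temporal profile × zero-mean level
contrast; doubly centered pattern for the interaction).  Because the
marginalization split is orthogonal, rescaling the loadings per
marginalization makes the population variance shares hit the requested
fractions *exactly* in the noiseless limit — `planted_fractions` is the
analytic oracle for all recovery tests.  Temporal profiles default to
random Gaussian bumps and sigmoidal ramps; tests plant explicit box
profiles when they need a known active window.  A grip-cluster mode ties
the first three of five levels to one profile and the last two to another,
emulating populations that separate grip groups rather than individual
grips.

Trial noise is Poisson (spike counts at the bin width, converted back to
Hz) or Gaussian; negative intensities are clipped at 0 Hz and the
generator warns when clipping touches > 0.1 % of entries, since
rectification perturbs the planted shares.

What the generator does *not* emulate: temporal noise correlations,
inter-neuron noise correlations (neurons are generated independently, as
pseudo-populations assume), firing-rate nonstationarity across trials, and
non-Poisson spiking statistics.  Passing recovery tests therefore
demonstrates correctness of the estimators under the planted model, not
fidelity to any particular cortical dataset.

### Noise tilt of raw variance shares

PSTH noise energy splits across marginalizations in proportion to subspace
dimension (≈ 17/33/17/33 % for a 3×2 design), so raw shares are pulled
toward that profile by the fraction of total energy that is noise.  With
Poisson noise the per-entry noise variance is `rate / (bin width · n
trials)`; at a plausible 10 Hz baseline this tilt alone exceeds the ±3-point
recovery tolerance.  Recovery tests therefore run in a high-SNR regime
(baseline 400 Hz, planted signal RMS 140 Hz) where the predicted tilt is
≈ 2 points and clipping stays near 1 % of entries.  This is a deliberate
choice of test regime, not a claim about biological rates.

## Decoding

Stratified Monte-Carlo leave-group-out CV: per iteration, one random trial
per neuron per condition is held out and assembled into per-condition
pseudo-trials; dPCA is refitted on the remaining-trial averages; test
pseudo-trials are classified at each bin by the nearest class centroid of
the training projections on the leading decoding axis of the target
marginalization (the number of axes is configurable; one axis is the default).  Chance level is `1/S` (`1/V` for the visual target).

Significance: condition labels are permuted across trials independently
within each neuron and the full pipeline re-run per shuffle; a bin is
significant when observed accuracy exceeds the `(1−α)` order-statistic
quantile of its null (the 95th of 100 shuffles at α = 0.05), and only runs
of ≥ 10 consecutive significant bins are reported.  The
minimum-population-size analysis repeats this for seeded neuron subsamples
(e.g. 100 plus a task-specific intermediate size), always including
the full population; a subsample of full size reuses the recording as-is
so it reproduces direct decoding bit-for-bit.

## Discrimination distance curves

For a 2-level factor, the projections of the leading component of that
factor's marginalization are averaged over the other factor's levels, and
the per-bin euclidean distance between the two level curves (absolute
difference for one component, k-dimensional norm for k) is the
discrimination curve.  Designs with more parameter levels are first
restricted to a chosen pair (left/right targets; whole-hand vs advanced
precision grips), giving a constant 2 × 2 design across tasks.

Confidence bands resample *neurons* with replacement (projections are population read-outs, so the neuron is the natural
resampling unit; trial-level resampling would require simultaneous
recordings) and refit the entire decomposition per resample — axes are estimates
too.  Bands are 2.5/97.5 percentiles of 100 resamples by default; bins
where the two curves' bands are disjoint for ≥ 10 consecutive bins are
separation intervals.

The randomization comparison of the two curves needs a null in which the
two factors play exchangeable roles.  A single global permutation of the
condition cells has essentially no power (a dominant effect lands in
*some* role under most permutations, so null differences match the
observed one in magnitude); instead, each neuron's 2 × 2 condition table
is independently transposed with probability 1/2 — an exact symmetry under
factor exchangeability that splits a dominant factor's energy between the
roles under the alternative.  Per-bin
`p = (1 + #{|null| ≥ |obs|}) / n_iter`, clipped at 1, so the smallest
attainable p is `1/n_iter`.

## Chi-squared comparisons of variance percentages

Each percentage is converted to `round(p)` hits out of a base of 100
counts per group and a Pearson chi-squared (no continuity correction by
default; a Yates flag exists) tests homogeneity of the groups × 2 table.
A variance percentage has no intrinsic sample size, so the count base is
an interpretive assumption — "percentage points out of 100" is the
convention this package adopts, and the base is exposed for sensitivity
checks.  The sampling
model behind a chi-squared on variance percentages is itself loose; the
test should be read as a conventional comparison procedure, not as a
calibrated inference.

## Problem sizes and determinism

Tests and the acceptance script run the full 175-bin designs with
populations of 40–150 neurons for module tests and 100–317 for the
end-to-end recovery runs, with 25 CV iterations × 25 shuffles for decoding
and 50 resamples for bootstrap/randomization; these sizes keep each check
well separated from its failure mode while remaining quick.  Every
stochastic step takes an explicit seed (child seeds derived via
`SeedSequence`), and identical configurations reproduce outputs
byte-for-byte.

## Known limitations

- Raw variance shares are noise-inflated (see the tilt analysis); no
  noise-floor correction is implemented.
- The decoding classifier is nearest-centroid on a 1-D projection by
  default; multi-axis or regularized classifiers are out of scope.
- Cross-validated selection of λ is available but off by default; no
  regularization path diagnostics.
- The chi-squared base-100 convention is an assumption, documented above.
- No probabilistic/Bayesian dPCA variants, trial-by-trial latent
  inference, or simultaneous-recording (noise-correlation-aware) decoding.
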