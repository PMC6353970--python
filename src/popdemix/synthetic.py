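"""Pseudo-population generator with planted marginalization variance shares.

Every neuron's noiseless rate is

    r_n(s, v, t) = baseline + sum_phi sum_k  w_{n,phi,k} * g_{phi,k}(s, v, t)

where each latent ``g`` lives entirely in one marginalization: the
condition-independent latents depend on time only; parameter latents are a
temporal profile times a zero-mean contrast over parameter levels; visual
latents a profile times a zero-mean contrast over the two visual conditions;
interaction latents a profile times a doubly-centered level-by-condition
pattern.  Because the marginalization split is an orthogonal projection,
each latent's energy lands exactly in its own part, so rescaling the
loadings per marginalization makes the population signal-variance shares
equal the requested fractions *exactly* in the noiseless limit — the
analytic recovery oracle for every downstream stage.

Trials add Poisson or Gaussian noise around the noiseless rate.  Negative
Poisson intensities are clipped at zero; clipping perturbs the planted
shares slightly, so a warning is emitted when it touches more than 0.1% of
entries and recovery tests should use baselines high enough to avoid it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .designs import (
    CONDITION_INDEPENDENT,
    INTERACTION,
    MARGINALIZATION_LABELS,
    PARAMETER,
    VISUAL,
    TaskDesign,
)
from .dpca import marginalize_array
from .recording import NeuronRecord, PopulationRecording, Trial

__all__ = ["EffectSpec", "generate_population", "planted_fractions", "noiseless_rates"]


@dataclass
class EffectSpec:
    """Recipe for a planted pseudo-population.

    Parameters
    ----------
    target_fractions : dict marginalization -> float
        Desired split of noiseless signal variance; must sum to 1.  Missing
        labels count as 0.
    n_latents : int
        Latents per (nonzero) marginalization.
    temporal_profiles : dict marginalization -> ndarray (n_latents, T), optional
        Explicit temporal profiles; marginalizations not listed get random
        smooth profiles (Gaussian bumps and ramps).
    level_weights : dict, optional
        Explicit level contrasts per marginalization: ``parameter`` maps to
        (n_latents, S), ``visual`` to (n_latents, 2), ``interaction`` to
        (n_latents, S, V); they are centered internally.  Random when absent.
    noise_model : {"poisson", "gaussian", "none"}
        Trial noise.  Poisson draws spike counts at the bin width and
        converts back to Hz; Gaussian adds ``noise_sigma_hz`` i.i.d. noise
        (clipped at 0 Hz).
    baseline_hz : float
        Mean firing rate added to every neuron.
    signal_std_hz : float
        Root-mean-square amplitude of the summed noiseless centered signal
        across all (neuron, condition, bin) entries.
    trials_per_condition : (int, int)
        Inclusive range of per-neuron, per-condition trial counts.
    grip_clusters : bool
        If set, parameter contrasts form two clusters over the levels (the
        first three levels share one value, the rest another), emulating
        populations that group prehension types rather than separating every
        level.
    seed : int
        Drives profiles, contrasts, loadings, trial counts and noise.
    """

    target_fractions: dict[str, float]
    n_latents: int = 2
    temporal_profiles: dict[str, np.ndarray] | None = None
    level_weights: dict[str, np.ndarray] | None = None
    noise_model: str = "poisson"
    noise_sigma_hz: float = 3.0
    baseline_hz: float = 10.0
    signal_std_hz: float = 5.0
    trials_per_condition: tuple[int, int] = (7, 15)
    grip_clusters: bool = False
    seed: int = 0

    def fractions(self) -> dict[str, float]:
        fr = {phi: float(self.target_fractions.get(phi, 0.0)) for phi in MARGINALIZATION_LABELS}
        unknown = set(self.target_fractions) - set(MARGINALIZATION_LABELS)
        if unknown:
            raise ValueError(f"unknown marginalization labels {sorted(unknown)}")
        if any(v < 0 for v in fr.values()):
            raise ValueError("variance fractions must be >= 0")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variance fractions sum to {total}, expected 1")
        return fr

    def validate(self, design: TaskDesign | None = None) -> None:
        self.fractions()
        if self.baseline_hz < 0:
            raise ValueError("baseline firing rate must be >= 0")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model == "poisson" and self.baseline_hz < 0:
            raise ValueError("Poisson noise requires a non-negative baseline")
        lo, hi = self.trials_per_condition
        if not (1 <= lo <= hi):
            raise ValueError("invalid trials_per_condition range")
        if self.signal_std_hz < 0:
            raise ValueError("signal amplitude must be >= 0")


def _random_profile(rng: np.random.Generator, T: int) -> np.ndarray:
    """A smooth temporal profile: Gaussian bump or sigmoidal ramp."""
    t = np.arange(T)
    if rng.random() < 0.6:
        center = rng.uniform(0.1 * T, 0.9 * T)
        width = rng.uniform(T / 20, T / 8)
        prof = np.exp(-0.5 * ((t - center) / width) ** 2)
    else:
        center = rng.uniform(0.2 * T, 0.8 * T)
        width = rng.uniform(T / 30, T / 10)
        prof = 1.0 / (1.0 + np.exp(-(t - center) / width))
    return prof


def _centered_contrast(rng: np.random.Generator, n: int) -> np.ndarray:
    for _ in range(100):
        c = rng.standard_normal(n)
        c -= c.mean()
        norm = np.linalg.norm(c)
        if norm > 1e-8:
            return c / norm
    raise RuntimeError("could not draw a non-degenerate contrast")


def _latents(
    design: TaskDesign, spec: EffectSpec, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Latent tensors g_{phi,k}(s, v, t), each exactly in its marginalization."""
    S, V, T = design.n_parameter_levels, design.n_visual_levels, design.n_bins
    fr = spec.fractions()
    nk = spec.n_latents
    profiles = dict(spec.temporal_profiles or {})
    weights = dict(spec.level_weights or {})
    out: dict[str, np.ndarray] = {}
    for phi in MARGINALIZATION_LABELS:
        if fr[phi] == 0:
            out[phi] = np.zeros((0, S, V, T))
            continue
        if phi in profiles:
            prof = np.atleast_2d(np.asarray(profiles[phi], float))
        else:
            prof = np.stack([_random_profile(rng, T) for _ in range(nk)])
        if prof.shape[1] != T:
            raise ValueError(f"temporal profile for {phi} has length {prof.shape[1]} != {T}")
        k = prof.shape[0]
        g = np.zeros((k, S, V, T))
        if phi == CONDITION_INDEPENDENT:
            g[:] = prof[:, None, None, :]
        elif phi == PARAMETER:
            if phi in weights:
                m = np.asarray(weights[phi], float)
            elif spec.grip_clusters:
                m = np.zeros((k, S))
                split = (S + 1) // 2
                for i in range(k):
                    a = rng.standard_normal()
                    m[i, :split] = a
                    m[i, split:] = -a * split / max(S - split, 1)
            else:
                m = np.stack([_centered_contrast(rng, S) for _ in range(k)])
            m = m - m.mean(axis=1, keepdims=True)
            g = np.broadcast_to(
                m[:, :, None, None] * prof[:, None, None, :], (k, S, V, T)
            ).copy()
        elif phi == VISUAL:
            if phi in weights:
                m = np.asarray(weights[phi], float)
            else:
                m = np.stack([_centered_contrast(rng, V) for _ in range(k)])
            m = m - m.mean(axis=1, keepdims=True)
            g = np.broadcast_to(
                m[:, None, :, None] * prof[:, None, None, :], (k, S, V, T)
            ).copy()
        else:  # interaction
            if phi in weights:
                M = np.asarray(weights[phi], float)
            else:
                M = np.stack(
                    [np.outer(_centered_contrast(rng, S), _centered_contrast(rng, V)) for _ in range(k)]
                )
            M = M - M.mean(axis=1, keepdims=True)
            M = M - M.mean(axis=2, keepdims=True)
            g = M[:, :, :, None] * prof[:, None, None, :]
        out[phi] = g
    return out


def _signal_tensor(
    design: TaskDesign, n_neurons: int, spec: EffectSpec, rng: np.random.Generator
) -> np.ndarray:
    """Noiseless centered-signal tensor with exact planted variance shares."""
    S, V, T = design.n_parameter_levels, design.n_visual_levels, design.n_bins
    fr = spec.fractions()
    latents = _latents(design, spec, rng)
    Y = np.zeros((n_neurons, S, V, T))
    size = n_neurons * S * V * T
    target_total = spec.signal_std_hz**2 * size
    for phi in MARGINALIZATION_LABELS:
        g = latents[phi]
        if g.shape[0] == 0 or fr[phi] == 0:
            continue
        w = rng.standard_normal((n_neurons, g.shape[0]))
        contrib = np.tensordot(w, g, axes=(1, 0))  # (N, S, V, T)
        # Energy of this contribution inside its own marginalization, after
        # per-neuron centering (relevant for condition-independent latents).
        centered = contrib - contrib.mean(axis=(1, 2, 3), keepdims=True)
        energy = float(np.sum(marginalize_array(centered)[phi] ** 2))
        if energy <= 0:
            raise ValueError(f"degenerate latent construction for {phi}")
        Y += contrib * np.sqrt(fr[phi] * target_total / energy)
    return Y


def noiseless_rates(design: TaskDesign, n_neurons: int, spec: EffectSpec) -> np.ndarray:
    """Noiseless rate tensor baseline + signal, shape (N, S, V, T)."""
    spec.validate(design)
    rng = np.random.default_rng(spec.seed)
    return spec.baseline_hz + _signal_tensor(design, n_neurons, spec, rng)


def planted_fractions(spec: EffectSpec, design: TaskDesign) -> dict[str, float]:
    """Analytic noiseless variance shares — the ground truth for recovery tests.

    Equals the requested ``target_fractions`` by construction (the generator
    rescales each marginalization's loadings to hit them exactly).
    """
    spec.validate(design)
    return spec.fractions()


def generate_population(
    design: TaskDesign, n_neurons: int, spec: EffectSpec
) -> PopulationRecording:
    """Draw a pseudo-population with planted variance structure.

    Deterministic given ``spec.seed``.  Trial counts per (neuron, condition)
    are uniform over ``spec.trials_per_condition``.
    """
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    spec.validate(design)
    rng = np.random.default_rng(spec.seed)
    S, V, T = design.n_parameter_levels, design.n_visual_levels, design.n_bins
    rates = spec.baseline_hz + _signal_tensor(design, n_neurons, spec, rng)

    clipped = rates < 0
    if clipped.mean() > 1e-3:
        warnings.warn(
            f"{100 * clipped.mean():.2f}% of noiseless rate entries are negative "
            "and were clipped at 0 Hz; planted variance shares are perturbed",
            stacklevel=2,
        )
    lam = np.clip(rates, 0.0, None)

    lo, hi = spec.trials_per_condition
    counts = rng.integers(lo, hi + 1, size=(n_neurons, S, V))
    bin_s = design.bin_width / 1000.0

    neurons = []
    for i in range(n_neurons):
        trials: list[Trial] = []
        for s, p_level in enumerate(design.parameter_levels):
            for v, v_level in enumerate(design.visual_levels):
                c = int(counts[i, s, v])
                mean = lam[i, s, v]
                if spec.noise_model == "poisson":
                    draws = rng.poisson(mean * bin_s, size=(c, T)) / bin_s
                elif spec.noise_model == "gaussian":
                    draws = mean[None, :] + rng.normal(0.0, spec.noise_sigma_hz, size=(c, T))
                    draws = np.clip(draws, 0.0, None)
                else:
                    draws = np.broadcast_to(mean, (c, T)).copy()
                for r in range(c):
                    trials.append(Trial(p_level, v_level, draws[r].astype(float)))
        neurons.append(NeuronRecord(neuron_id=f"n{i:04d}", trials=trials))
    return PopulationRecording(
        design=design, neurons=neurons, min_trials=lo, max_trials=hi
    )
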