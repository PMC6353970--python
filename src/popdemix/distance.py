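"""Discrimination time-courses: euclidean distances between level-averaged
component projections, with bootstrap confidence bands and a randomization
comparison of the two factors.

For a 2-level factor the projections of the leading component of that
factor's marginalization are averaged over the other factor's levels (e.g.
the "left" curve is the mean of left-in-light and left-in-dark), and the
per-bin euclidean distance between the two level curves measures how well
the population separates the factor at each moment of the trial.  Doing
this for the task parameter and for the visual condition yields two curves
on a common time axis.

Confidence bands resample *neurons* with replacement and refit the whole
decomposition per resample (the axes are estimates too); the two curves are
declared separated where their 95% bands do not overlap for at least 10
consecutive bins.  The randomization test builds its null by randomly
swapping the factor-role assignment of the conditions — each neuron's 2x2
condition table is transposed with probability 1/2, the exchangeability
symmetry under "both factors play the same role" — and recomputing the
difference of the two curves.  Designs with more than two parameter levels
are first restricted to the chosen pair, so the comparison always runs on a
constant 2 x 2 design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._utils import find_runs, spawn_seeds
from .designs import PARAMETER, VISUAL, TaskDesign
from .dpca import DPCAResult, fit_dpca, project_conditions
from .recording import (
    PopulationRecording,
    RateTensor,
    build_rate_tensor,
    subset_conditions,
)

__all__ = [
    "DistanceCurveResult",
    "averaged_projections",
    "distance_curve",
    "factor_distance_curves",
    "bootstrap_bands",
    "randomization_compare",
]

_FACTOR_MARG = {"parameter": PARAMETER, "visual": VISUAL}


@dataclass
class DistanceCurveResult:
    """Two discrimination curves with CI bands and significance intervals."""

    parameter_curve: np.ndarray
    visual_curve: np.ndarray
    parameter_ci: tuple[np.ndarray, np.ndarray] | None = None  # (lower, upper)
    visual_ci: tuple[np.ndarray, np.ndarray] | None = None
    separation_intervals: list[tuple[int, int]] = field(default_factory=list)
    n_bootstrap: int = 0
    p_values: np.ndarray | None = None
    randomization_intervals: list[tuple[int, int]] = field(default_factory=list)
    n_randomization: int = 0
    parameter_levels: tuple[str, str] = ("", "")
    epoch_boundaries: tuple[int, ...] = ()


def averaged_projections(
    result: DPCAResult,
    Xc,
    factor: str,
    levels: tuple[str, str] | None = None,
    n_components: int = 1,
) -> dict[str, np.ndarray]:
    """Level curves of a factor: leading-component projections averaged over
    the other factor's levels.

    Returns ``{level: curve}`` with curves of shape (n_components, T).
    """
    if factor not in _FACTOR_MARG:
        raise ValueError("factor must be 'parameter' or 'visual'")
    design = result.design
    if design is None:
        raise ValueError("result carries no design; fit on a RateTensor")
    proj = project_conditions(result, Xc)  # (n_comp, S, V, T)
    marg = _FACTOR_MARG[factor]
    comp_idx = [
        j for j, phi in enumerate(result.marginalization_of_component) if phi == marg
    ][:n_components]
    if len(comp_idx) < n_components:
        raise ValueError(f"fewer than {n_components} components for {marg}")
    sel = proj[comp_idx]  # (k, S, V, T)
    if factor == "parameter":
        all_levels = design.parameter_levels
        per_level = sel.mean(axis=2)  # average over visual -> (k, S, T)
    else:
        all_levels = design.visual_levels
        per_level = sel.mean(axis=1)  # average over parameter -> (k, V, T)
    levels = tuple(levels) if levels is not None else tuple(all_levels[:2])
    out = {}
    for level in levels:
        if level not in all_levels:
            raise KeyError(f"level {level!r} not in {all_levels}")
        out[level] = per_level[:, all_levels.index(level), :]
    return out


def distance_curve(curve_a: np.ndarray, curve_b: np.ndarray) -> np.ndarray:
    """Per-bin euclidean distance between two (k, T) or (T,) curves.

    With a single component this is the absolute per-bin difference; with k
    components the k-dimensional euclidean norm per bin.
    """
    a = np.atleast_2d(np.asarray(curve_a, float))
    b = np.atleast_2d(np.asarray(curve_b, float))
    if a.shape != b.shape:
        raise ValueError(f"curve shapes differ: {a.shape} vs {b.shape}")
    return np.linalg.norm(a - b, axis=0)


def factor_distance_curves(
    result: DPCAResult,
    Xc,
    parameter_levels: tuple[str, str] | None = None,
    n_components: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """(parameter curve, visual curve) for a fitted decomposition."""
    p = averaged_projections(result, Xc, "parameter", parameter_levels, n_components)
    v = averaged_projections(result, Xc, "visual", None, n_components)
    (pa, pb), (va, vb) = list(p.values()), list(v.values())
    return distance_curve(pa, pb), distance_curve(va, vb)


def _fit_curves(
    Xc: np.ndarray,
    design: TaskDesign,
    parameter_levels,
    n_components: int,
    q: int,
    reg,
) -> tuple[np.ndarray, np.ndarray]:
    tensor = RateTensor(
        design=design, X=Xc, neuron_means=np.zeros(Xc.shape[0])
    )
    res = fit_dpca(tensor, q_per_marginalization=q, reg=reg)
    return factor_distance_curves(res, Xc, parameter_levels, n_components)


def _as_pair_tensor(
    recording: PopulationRecording | RateTensor,
    parameter_levels: tuple[str, str] | None,
) -> tuple[RateTensor, tuple[str, str]]:
    """Tensor restricted to two parameter levels (the constant 2x2 design)."""
    tensor = (
        recording
        if isinstance(recording, RateTensor)
        else build_rate_tensor(recording, keep_trials=False)
    )
    if parameter_levels is None:
        parameter_levels = tensor.design.parameter_levels[:2]
    parameter_levels = tuple(parameter_levels)
    if len(parameter_levels) != 2:
        raise ValueError("exactly two parameter levels are compared")
    if parameter_levels != tensor.design.parameter_levels:
        tensor = subset_conditions(tensor, parameter_levels)
    return tensor, parameter_levels


def bootstrap_bands(
    recording: PopulationRecording | RateTensor,
    parameter_levels: tuple[str, str] | None = None,
    n_bootstrap: int = 100,
    seed: int = 0,
    n_components: int = 1,
    q_per_marginalization: int = 5,
    reg="auto",
    ci: float = 0.95,
    min_consecutive: int = 10,
) -> DistanceCurveResult:
    """Neuron-bootstrap confidence bands and CI-separation intervals.

    Neurons are resampled with replacement and the decomposition is refitted
    per resample; bands are the 2.5/97.5 percentile of the resampled curves.
    A bin is separated when the two curves' bands are disjoint; intervals
    are runs of >= ``min_consecutive`` separated bins within an epoch.
    """
    if n_bootstrap < 20:
        warnings.warn("fewer than 20 bootstrap resamples: bands are unstable", stacklevel=2)
    tensor, parameter_levels = _as_pair_tensor(recording, parameter_levels)
    design = tensor.design
    Xc = tensor.centered()
    p_curve, v_curve = _fit_curves(
        Xc, design, parameter_levels, n_components, q_per_marginalization, reg
    )

    N = Xc.shape[0]
    rng = np.random.default_rng(seed)
    boot = np.empty((n_bootstrap, 2, p_curve.shape[0]))
    for b in range(n_bootstrap):
        idx = rng.integers(0, N, size=N)
        Xb = Xc[idx]
        Xb = Xb - Xb.mean(axis=(1, 2, 3), keepdims=True)
        boot[b, 0], boot[b, 1] = _fit_curves(
            Xb, design, parameter_levels, n_components, q_per_marginalization, reg
        )
    lo = (1.0 - ci) / 2.0
    p_lo, p_hi = np.quantile(boot[:, 0], [lo, 1 - lo], axis=0)
    v_lo, v_hi = np.quantile(boot[:, 1], [lo, 1 - lo], axis=0)
    separated = (p_lo > v_hi) | (v_lo > p_hi)
    intervals = find_runs(separated, min_consecutive, design.epoch_boundaries)
    return DistanceCurveResult(
        parameter_curve=p_curve,
        visual_curve=v_curve,
        parameter_ci=(p_lo, p_hi),
        visual_ci=(v_lo, v_hi),
        separation_intervals=intervals,
        n_bootstrap=n_bootstrap,
        parameter_levels=tuple(parameter_levels),
        epoch_boundaries=design.epoch_boundaries,
    )


def randomization_compare(
    recording: PopulationRecording | RateTensor,
    parameter_levels: tuple[str, str] | None = None,
    n_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_components: int = 1,
    q_per_marginalization: int = 5,
    reg="auto",
    min_consecutive: int = 10,
) -> DistanceCurveResult:
    """Randomization test of the difference between the two distance curves.

    The null randomly swaps the factor-role assignment of the conditions:
    each neuron's 2x2 condition table is transposed with probability 1/2
    (exchanging which factor is "parameter" and which is "visual" for that
    neuron), and both curves are recomputed.  Under exchangeable factors
    this is a symmetry of the data; when one factor truly dominates, the
    transposed populations split its energy between the two roles and the
    observed difference stands out.  Per-bin
    ``p = (1 + #{|null| >= |observed|}) / n_iter`` (clipped at 1, so the
    smallest attainable p is 1/n_iter); intervals are runs of >=
    ``min_consecutive`` bins with p < alpha.
    """
    tensor, parameter_levels = _as_pair_tensor(recording, parameter_levels)
    design = tensor.design
    Xc = tensor.centered()
    pair = design.parameter_levels
    p_curve, v_curve = _fit_curves(
        Xc, design, pair, n_components, q_per_marginalization, reg
    )
    observed = p_curve - v_curve

    N, S, V, T = Xc.shape
    # Transposing the (s, v) table requires a square factor layout; the
    # pair restriction above guarantees 2 x 2.
    Xt = np.swapaxes(Xc, 1, 2)
    rng = np.random.default_rng(seed)
    null = np.empty((n_iter, T))
    for k in range(n_iter):
        flip = rng.random(N) < 0.5
        Xp = np.where(flip[:, None, None, None], Xt, Xc)
        pk, vk = _fit_curves(
            Xp, design, pair, n_components, q_per_marginalization, reg
        )
        null[k] = pk - vk
    exceed = (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)
    p_values = np.minimum(1.0, (1.0 + exceed) / n_iter)
    intervals = find_runs(p_values < alpha, min_consecutive, design.epoch_boundaries)
    return DistanceCurveResult(
        parameter_curve=p_curve,
        visual_curve=v_curve,
        p_values=p_values,
        randomization_intervals=intervals,
        n_randomization=n_iter,
        parameter_levels=tuple(parameter_levels),
        epoch_boundaries=design.epoch_boundaries,
    )
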