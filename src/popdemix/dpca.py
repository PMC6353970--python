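"""Demixed principal component analysis by per-marginalization reduced-rank ridge.

The centered PSTH tensor ``Xc`` (neurons x parameter levels x visual
conditions x time) is first split exactly into four ANOVA-style parts —
condition-independent, task parameter, visual condition and their
interaction — that sum back to ``Xc``.  For each part ``X_phi`` the method
then minimizes

    || X_phi - F_phi D_phi X ||^2 + lambda || F_phi D_phi ||^2

over rank-constrained encoder/decoder pairs: the full-rank ridge solution
``A_phi = X_phi X^T (X X^T + lambda I)^-1`` is rank-reduced by truncating the
SVD of ``A_phi X``; the top left singular vectors give the (unit-norm)
encoder columns and ``D_phi = F_phi^T A_phi``.  Decoder rows are *not*
mutually orthogonal — that freedom is what lets components demix: each one
reads out variance belonging to a single marginalization while the set still
compresses the data almost as well as ordinary PCA.

Components are ordered globally by explained variance.  Signs are fixed so
the time-averaged projection of the first condition is non-negative (signs
are arbitrary; a convention keeps results deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .designs import (
    CONDITION_INDEPENDENT,
    INTERACTION,
    MARGINALIZATION_LABELS,
    PARAMETER,
    VISUAL,
    TaskDesign,
)
from .recording import RateTensor

__all__ = [
    "MarginalizedData",
    "DPCAResult",
    "DemixedPCA",
    "marginalize",
    "marginalize_array",
    "fit_dpca",
    "fit_pca",
    "explained_variance_split",
    "project_conditions",
]


def _as_centered_array(Xc, atol: float = 1e-6) -> np.ndarray:
    if isinstance(Xc, RateTensor):
        return Xc.centered()
    X = np.asarray(Xc, float)
    if X.ndim != 4:
        raise ValueError("expected a tensor of shape (N, S, V, T)")
    means = X.mean(axis=(1, 2, 3))
    if np.abs(means).max() > atol:
        raise ValueError(
            "input tensor is not centered per neuron "
            f"(max |neuron mean| = {np.abs(means).max():.3g} Hz); center it first"
        )
    return X


@dataclass
class MarginalizedData:
    """Exact additive split of a centered tensor into the four marginalizations."""

    parts: dict[str, np.ndarray]

    def total(self) -> np.ndarray:
        return sum(self.parts.values())

    def energies(self) -> dict[str, float]:
        """Squared Frobenius norm of each part (the signal-variance split)."""
        return {k: float(np.sum(v**2)) for k, v in self.parts.items()}


def marginalize_array(Xc: np.ndarray) -> dict[str, np.ndarray]:
    """ANOVA decomposition of a centered (N, S, V, T) tensor.

    condition-independent = mean over (s, v); parameter = mean over v minus
    that; visual = mean over s minus that; interaction = remainder.  The
    parts are orthogonal projections, sum to the input exactly, and each
    averages to zero over the factors it does not depend on.
    """
    ci = Xc.mean(axis=(1, 2), keepdims=True)
    param = Xc.mean(axis=2, keepdims=True) - ci
    visual = Xc.mean(axis=1, keepdims=True) - ci
    inter = Xc - ci - param - visual
    shape = Xc.shape
    return {
        CONDITION_INDEPENDENT: np.broadcast_to(ci, shape).copy(),
        PARAMETER: np.broadcast_to(param, shape).copy(),
        VISUAL: np.broadcast_to(visual, shape).copy(),
        INTERACTION: inter,
    }


def marginalize(Xc) -> MarginalizedData:
    """Split a centered tensor (or RateTensor) into its four marginalizations.

    Raises if any neuron mean exceeds 1e-6 Hz in magnitude.
    """
    return MarginalizedData(parts=marginalize_array(_as_centered_array(Xc)))


def explained_variance_split(Xc) -> dict[str, float]:
    """Percentage of total signal variance per marginalization.

    ``100 * ||X_phi||^2 / sum_psi ||X_psi||^2`` on the centered tensor; raw
    shares, no noise-floor correction.  Full precision is returned; round for
    reporting.
    """
    energies = marginalize(Xc).energies()
    total = sum(energies.values())
    if total == 0:
        raise ValueError("tensor has zero variance")
    return {k: 100.0 * v / total for k, v in energies.items()}


# ---------------------------------------------------------------------------
# PCA baseline


def fit_pca(Xc, q: int):
    """Standard PCA on the N x (S*V*T) unfolding.

    Returns ``(axes, cumulative_variance)`` where ``axes`` is (q, N) with
    orthonormal rows and ``cumulative_variance`` the non-decreasing fraction
    of total variance explained by the first 1..q components.
    """
    X = _as_centered_array(Xc)
    N = X.shape[0]
    K = int(np.prod(X.shape[1:]))
    if not (1 <= q <= min(N, K)):
        raise ValueError(f"q={q} out of range [1, {min(N, K)}]")
    # Samples are condition-time points, features are neurons; the feature
    # means sklearn removes are the per-neuron means, which are already zero.
    pca = PCA(n_components=q, svd_solver="full")
    pca.fit(X.reshape(N, K).T)
    cumulative = np.cumsum(pca.explained_variance_ratio_)
    return pca.components_, cumulative


# ---------------------------------------------------------------------------
# dPCA


@dataclass
class DPCAResult:
    """Fitted demixed PCA: axes, variance accounting and condition projections.

    ``decoders[phi]`` has shape (q_phi, N) (rows not mutually orthogonal),
    ``encoders[phi]`` shape (N, q_phi) with unit-norm columns.  Global
    component order (by explained variance) is given by ``component_order``,
    a list of ``(marginalization, within-marginalization index)`` pairs;
    ``projections`` is (n_components, S, V, T) in that order.
    """

    design: TaskDesign | None
    decoders: dict[str, np.ndarray]
    encoders: dict[str, np.ndarray]
    reg: float
    component_order: list[tuple[str, int]]
    marginalization_of_component: list[str]
    component_variances: np.ndarray  # fraction of total signal variance
    projections: np.ndarray
    cumulative_variance_dpca: np.ndarray
    cumulative_variance_pca: np.ndarray
    total_variance: float
    variance_split: dict[str, float]

    @property
    def n_components(self) -> int:
        return len(self.component_order)

    def ordered_decoders(self) -> np.ndarray:
        """Decoder rows stacked in global component order, shape (n_comp, N)."""
        return np.stack(
            [self.decoders[phi][i] for phi, i in self.component_order]
        )

    def leading_component(self, marginalization: str) -> int:
        """Global index of the highest-variance component of a marginalization."""
        for j, phi in enumerate(self.marginalization_of_component):
            if phi == marginalization:
                return j
        raise KeyError(f"no component for marginalization {marginalization!r}")


def _auto_reg(Xmat: np.ndarray) -> float:
    return 1e-6 * float(np.sum(Xmat**2)) / Xmat.size


def _fit_dpca_arrays(
    Xc: np.ndarray,
    q_per_marginalization: dict[str, int],
    reg,
) -> DPCAResult:
    N, S, V, T = Xc.shape
    K = S * V * T
    Xmat = Xc.reshape(N, K)
    total = float(np.sum(Xmat**2))
    if total == 0:
        raise ValueError("tensor has zero variance")

    lam = _auto_reg(Xmat) if reg == "auto" else float(reg)
    if lam < 0:
        raise ValueError("ridge strength must be >= 0")
    if lam == 0 and N > K:
        raise ValueError(
            "X X^T is singular (more neurons than condition-time points); "
            "use a ridge strength lambda > 0"
        )

    parts = marginalize_array(Xc)
    G = Xmat @ Xmat.T
    Greg = G + lam * np.eye(N)
    # Pseudo-inverse: equals the inverse whenever lambda > 0 (or X has full
    # row rank) and gives the minimum-norm ridge solution on exactly
    # low-rank data, where X X^T is singular at lambda = 0.
    Ginv = np.linalg.pinv(Greg, hermitian=True)

    decoders: dict[str, np.ndarray] = {}
    encoders: dict[str, np.ndarray] = {}
    variances: dict[str, np.ndarray] = {}
    for phi in MARGINALIZATION_LABELS:
        q = int(q_per_marginalization[phi])
        if q < 1:
            raise ValueError("at least 1 component per marginalization")
        q = min(q, N, K)
        Pmat = parts[phi].reshape(N, K)
        A = (Pmat @ Xmat.T) @ Ginv
        M = A @ Xmat
        U, svals, _ = np.linalg.svd(M, full_matrices=False)
        F = U[:, :q]
        D = F.T @ A
        Z = D @ Xmat  # projections of the full data
        # Sign convention: time-average of the first condition's projection >= 0.
        first = Z.reshape(q, S, V, T)[:, 0, 0, :].mean(axis=1)
        flip = np.where(first < 0, -1.0, 1.0)
        F = F * flip[None, :]
        D = D * flip[:, None]
        decoders[phi] = D
        encoders[phi] = F
        # Encoder columns are unit norm, so each component's reconstruction
        # f_i (d_i X) carries energy ||d_i X||^2.
        variances[phi] = np.sum((D @ Xmat) ** 2, axis=1) / total

    order: list[tuple[str, int]] = [
        (phi, i) for phi in MARGINALIZATION_LABELS for i in range(len(variances[phi]))
    ]
    order.sort(key=lambda t: variances[t[0]][t[1]], reverse=True)
    component_variances = np.array([variances[phi][i] for phi, i in order])
    marg_of_component = [phi for phi, _ in order]

    D_all = np.stack([decoders[phi][i] for phi, i in order])
    F_all = np.stack([encoders[phi][:, i] for phi, i in order], axis=1)
    Z_all = D_all @ Xmat
    projections = Z_all.reshape(len(order), S, V, T)

    # Cumulative variance: 1 - ||X - F_{1:q} D_{1:q} X||^2 / ||X||^2.
    n_comp = len(order)
    cumulative = np.empty(n_comp)
    recon = np.zeros_like(Xmat)
    for j in range(n_comp):
        recon += np.outer(F_all[:, j], Z_all[j])
        cumulative[j] = 1.0 - float(np.sum((Xmat - recon) ** 2)) / total

    q_pca = min(n_comp, N, K)
    _, cum_pca = fit_pca(Xc, q_pca)
    if q_pca < n_comp:  # PCA saturates at min(N, K) components
        cum_pca = np.concatenate([cum_pca, np.full(n_comp - q_pca, cum_pca[-1])])

    energies = {k: float(np.sum(v**2)) for k, v in parts.items()}
    tot_e = sum(energies.values())
    split = {k: 100.0 * v / tot_e for k, v in energies.items()}

    return DPCAResult(
        design=None,
        decoders=decoders,
        encoders=encoders,
        reg=lam,
        component_order=order,
        marginalization_of_component=marg_of_component,
        component_variances=component_variances,
        projections=projections,
        cumulative_variance_dpca=cumulative,
        cumulative_variance_pca=cum_pca,
        total_variance=total,
        variance_split=split,
    )


def _normalize_q(q_per_marginalization) -> dict[str, int]:
    if isinstance(q_per_marginalization, dict):
        q = {phi: int(q_per_marginalization.get(phi, 10)) for phi in MARGINALIZATION_LABELS}
    else:
        q = {phi: int(q_per_marginalization) for phi in MARGINALIZATION_LABELS}
    return q


def fit_dpca(Xc, q_per_marginalization=10, reg="auto") -> DPCAResult:
    """Fit demixed PCA on a centered tensor or RateTensor.

    Parameters
    ----------
    q_per_marginalization : int or dict label -> int, default 10
        Components retained per marginalization.
    reg : float or "auto"
        Ridge strength lambda; "auto" uses ``1e-6 * ||X||^2 / size`` as a
        numerical stabilizer.
    """
    design = Xc.design if isinstance(Xc, RateTensor) else None
    result = _fit_dpca_arrays(_as_centered_array(Xc), _normalize_q(q_per_marginalization), reg)
    result.design = design
    return result


def project_conditions(result: DPCAResult, Xc) -> np.ndarray:
    """Project each condition's PSTH onto every decoding axis.

    Returns (n_components, S, V, T) in global component order: the S*V
    condition time-courses of every component.
    """
    X = _as_centered_array(Xc)
    N = X.shape[0]
    Z = result.ordered_decoders() @ X.reshape(N, -1)
    return Z.reshape(result.n_components, *X.shape[1:])


def select_reg(
    tensor: RateTensor,
    candidates=None,
    q_per_marginalization=10,
    n_splits: int = 3,
    seed: int = 0,
) -> float:
    """Cross-validated ridge-strength selection (off by default in fits).

    For each split, one random trial per neuron per condition is held out;
    dPCA is fitted on the remaining-trial averages at each candidate lambda
    and scored by the per-marginalization reconstruction error of the
    held-out PSTH tensor, ``sum_phi ||Xtest_phi - F_phi D_phi Xtest||^2``.
    Returns the candidate with the smallest mean error.
    """
    if tensor.trial_tensor is None:
        raise ValueError("lambda selection needs the trial-resolved tensor")
    counts = tensor.trial_counts()
    if np.any(counts < 2):
        raise ValueError("lambda selection needs >= 2 trials per condition")
    X = tensor.X
    N = X.shape[0]
    scale = float(np.sum((X - X.mean(axis=(1, 2, 3), keepdims=True)) ** 2))
    if candidates is None:
        candidates = [0.0] + [scale * 10.0**e for e in range(-10, -2)]
    candidates = [float(c) for c in candidates]
    q = _normalize_q(q_per_marginalization)
    rng = np.random.default_rng(seed)
    sums = tensor.trial_tensor.sum(axis=-1)
    errors = np.zeros(len(candidates))
    for _ in range(n_splits):
        j = (rng.random(size=counts.shape) * counts).astype(int)
        test = np.take_along_axis(
            tensor.trial_tensor, j[:, :, :, None, None], axis=-1
        )[..., 0]
        train = (sums - test) / (counts - 1)[..., None]
        mu = train.mean(axis=(1, 2, 3), keepdims=True)
        Xc_train = train - mu
        Xc_test = test - mu
        test_parts = marginalize_array(
            Xc_test - Xc_test.mean(axis=(1, 2, 3), keepdims=True)
        )
        Xmat_test = Xc_test.reshape(N, -1)
        for i, lam in enumerate(candidates):
            if lam == 0 and N > Xmat_test.shape[1]:
                errors[i] = np.inf
                continue
            res = _fit_dpca_arrays(Xc_train, q, lam)
            for phi in MARGINALIZATION_LABELS:
                recon = res.encoders[phi] @ (res.decoders[phi] @ Xmat_test)
                errors[i] += float(
                    np.sum((test_parts[phi].reshape(N, -1) - recon) ** 2)
                )
    return candidates[int(np.argmin(errors))]


class DemixedPCA(BaseEstimator):
    """sklearn-style estimator wrapper around :func:`fit_dpca`.

    ``fit`` accepts a :class:`~popdemix.recording.RateTensor` or an ndarray
    of shape (N, S, V, T); uncentered arrays are centered per neuron as part
    of fitting.  ``transform`` returns condition projections of shape
    (n_components, S, V, T).

    Attributes (after ``fit``)
    --------------------------
    decoders_, encoders_ : dict marginalization -> ndarray
    component_variances_ : ndarray, fraction of total signal variance
    marginalization_of_component_ : list of str
    projections_ : ndarray (n_components, S, V, T)
    cumulative_variance_, cumulative_variance_pca_ : ndarray
    variance_split_ : dict marginalization -> percentage
    result_ : DPCAResult
    """

    def __init__(self, n_components=10, reg="auto"):
        self.n_components = n_components
        self.reg = reg

    def _validate_input(self, X) -> tuple[np.ndarray, TaskDesign | None]:
        if isinstance(X, RateTensor):
            return X.centered(), X.design
        arr = np.asarray(X, float)
        if arr.ndim != 4:
            raise ValueError("expected a tensor of shape (N, S, V, T)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("input contains non-finite values")
        return arr - arr.mean(axis=(1, 2, 3), keepdims=True), None

    def fit(self, X, y=None):
        Xc, design = self._validate_input(X)
        result = _fit_dpca_arrays(Xc, _normalize_q(self.n_components), self.reg)
        result.design = design
        self.result_ = result
        self.n_features_in_ = Xc.shape[0]
        self.decoders_ = result.decoders
        self.encoders_ = result.encoders
        self.reg_ = result.reg
        self.component_variances_ = result.component_variances
        self.marginalization_of_component_ = result.marginalization_of_component
        self.projections_ = result.projections
        self.cumulative_variance_ = result.cumulative_variance_dpca
        self.cumulative_variance_pca_ = result.cumulative_variance_pca
        self.variance_split_ = result.variance_split
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise AttributeError("DemixedPCA instance is not fitted yet")
        Xc, _ = self._validate_input(X)
        if Xc.shape[0] != self.n_features_in_:
            raise ValueError(
                f"tensor has {Xc.shape[0]} neurons, estimator was fitted on "
                f"{self.n_features_in_}"
            )
        return project_conditions(self.result_, Xc)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).projections_
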