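"""Time-resolved population decoding from dPCA decoding axes.

Stratified Monte-Carlo leave-group-out cross-validation: on each iteration
one random trial per neuron per condition is held out; the remaining trials
are averaged into a training PSTH tensor, demixed PCA is fitted on it, and
the held-out trials are assembled into per-condition "pseudo-trial"
population vectors (neurons were recorded separately, so pseudo-trials pair
same-condition trials across neurons).  Each pseudo-trial is classified at
every time bin by the nearest class centroid of the training projections on
the leading decoding axis (or axes) of the target marginalization — the
decoding axes themselves act as the linear classifier.

Chance level is 1/S for a task-parameter target (1/V for the visual
target).  Significance uses a shuffle null: condition labels are permuted
across trials independently within each neuron and the whole decoding
pipeline is re-run; a bin counts as significant when observed accuracy
exceeds the upper order-statistic quantile of its null, and only runs of at
least ``min_consecutive`` significant bins (never spanning an alignment
epoch boundary) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import find_runs, order_statistic_quantile, spawn_seeds
from .designs import PARAMETER, VISUAL
from .dpca import marginalize_array
from .recording import PopulationRecording, RateTensor, build_rate_tensor, subsample_neurons

__all__ = [
    "DecodingResult",
    "decode_timecourse",
    "significance_intervals",
    "min_population_analysis",
]


@dataclass
class DecodingResult:
    """Cross-validated decoding accuracy and (optionally) its shuffle null."""

    accuracy: np.ndarray  # (T,) mean accuracy per bin
    n_iterations: int
    target: str
    chance_level: float
    population_size: int
    seed: int
    q_axes: int
    reg: object
    null_accuracies: np.ndarray | None = None  # (n_shuffles, T)
    null_threshold: np.ndarray | None = None  # (T,) upper quantile of the null
    significant_intervals: list[tuple[int, int]] = field(default_factory=list)
    epoch_boundaries: tuple[int, ...] = ()

    def total_significant_bins(self) -> int:
        return sum(stop - start for start, stop in self.significant_intervals)


def _target_part(Xc: np.ndarray, target: str) -> np.ndarray:
    parts = marginalize_array(Xc)
    return parts[PARAMETER] if target == PARAMETER else parts[VISUAL]


def _fit_target_axes(Xc: np.ndarray, target: str, q_axes: int, reg) -> np.ndarray:
    """Leading decoding axes (q_axes, N) of the target marginalization."""
    N = Xc.shape[0]
    K = int(np.prod(Xc.shape[1:]))
    Xmat = Xc.reshape(N, K)
    lam = 1e-6 * float(np.sum(Xmat**2)) / Xmat.size if reg == "auto" else float(reg)
    if lam == 0 and N > K:
        raise ValueError("X X^T is singular; use a ridge strength lambda > 0")
    Pmat = _target_part(Xc, target).reshape(N, K)
    G = Xmat @ Xmat.T + lam * np.eye(N)
    A = np.linalg.solve(G, Xmat @ Pmat.T).T
    M = A @ Xmat
    U, _, _ = np.linalg.svd(M, full_matrices=False)
    return U[:, :q_axes].T @ A


def _prepare(recording_or_tensor) -> RateTensor:
    if isinstance(recording_or_tensor, RateTensor):
        tensor = recording_or_tensor
    else:
        tensor = build_rate_tensor(recording_or_tensor, keep_trials=True)
    if tensor.trial_tensor is None:
        raise ValueError("decoding needs the trial-resolved tensor")
    counts = tensor.trial_counts()
    if np.any(counts < 2):
        i, s, v = map(int, np.argwhere(counts < 2)[0])
        name = tensor.neuron_ids[i] if tensor.neuron_ids else str(i)
        d = tensor.design
        raise ValueError(
            f"neuron {name} has fewer than 2 trials for condition "
            f"({d.parameter_levels[s]}, {d.visual_levels[v]}); "
            "cross-validation needs >= 2"
        )
    return tensor


def _decode_accuracy(
    trial_tensor: np.ndarray,
    counts: np.ndarray,
    target: str,
    n_iterations: int,
    q_axes: int,
    reg,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean per-bin accuracy over CV iterations for one (possibly shuffled) dataset."""
    N, S, V, T, _ = trial_tensor.shape
    sums = trial_tensor.sum(axis=-1)  # (N, S, V, T)
    n_classes = S if target == PARAMETER else V
    correct = np.zeros(T)
    total = 0
    for _ in range(n_iterations):
        # Hold out one random trial per neuron per condition (valid slots
        # are contiguous from 0, so a uniform index below the count works).
        j = (rng.random(size=(N, S, V)) * counts).astype(int)
        test = np.take_along_axis(
            trial_tensor, j[:, :, :, None, None], axis=-1
        )[..., 0]  # (N, S, V, T)
        X_train = (sums - test) / (counts - 1)[..., None]
        mu = X_train.mean(axis=(1, 2, 3), keepdims=True)
        Xc = X_train - mu
        D = _fit_target_axes(Xc, target, q_axes, reg)  # (q, N)
        Ztrain = (D @ Xc.reshape(N, -1)).reshape(-1, S, V, T)
        if target == PARAMETER:
            centroids = Ztrain.mean(axis=2)  # (q, S, T)
        else:
            centroids = Ztrain.mean(axis=1)  # (q, V, T)
        Ztest = (D @ (test - mu).reshape(N, -1)).reshape(-1, S, V, T)
        # (q, S, V, C, T) squared distances to each class centroid
        dist = (Ztest[:, :, :, None, :] - centroids[:, None, None, :, :]) ** 2
        pred = dist.sum(axis=0).argmin(axis=2)  # (S, V, T)
        truth = (
            np.arange(S)[:, None, None] if target == PARAMETER else np.arange(V)[None, :, None]
        )
        correct += (pred == truth).sum(axis=(0, 1))
        total += S * V
    return correct / total


def decode_timecourse(
    recording: PopulationRecording | RateTensor,
    target: str = PARAMETER,
    n_iterations: int = 100,
    q_axes: int = 1,
    reg="auto",
    seed: int = 0,
) -> DecodingResult:
    """Cross-validated per-bin decoding accuracy of the task parameter (or
    visual condition) from the leading target-marginalization decoding axes.
    Deterministic given ``seed``."""
    if target not in (PARAMETER, VISUAL):
        raise ValueError(f"target must be {PARAMETER!r} or {VISUAL!r}")
    tensor = _prepare(recording)
    counts = tensor.trial_counts()
    rng = np.random.default_rng(seed)
    accuracy = _decode_accuracy(
        tensor.trial_tensor, counts, target, n_iterations, q_axes, reg, rng
    )
    d = tensor.design
    chance = 1.0 / (d.n_parameter_levels if target == PARAMETER else d.n_visual_levels)
    return DecodingResult(
        accuracy=accuracy,
        n_iterations=n_iterations,
        target=target,
        chance_level=chance,
        population_size=tensor.n_neurons,
        seed=seed,
        q_axes=q_axes,
        reg=reg,
        epoch_boundaries=d.epoch_boundaries,
    )


def _shuffle_labels(
    trial_tensor: np.ndarray, counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Permute condition labels across trials independently within each neuron."""
    N, S, V, T, R = trial_tensor.shape
    out = np.zeros_like(trial_tensor)
    flat_counts = counts.reshape(N, S * V)
    for n in range(N):
        pool = [
            trial_tensor[n].reshape(S * V, T, R)[c, :, :flat_counts[n, c]].T
            for c in range(S * V)
        ]
        pool = np.concatenate(pool, axis=0)  # (n_trials, T)
        pool = pool[rng.permutation(pool.shape[0])]
        ofs = 0
        flat = out[n].reshape(S * V, T, R)
        for c in range(S * V):
            k = flat_counts[n, c]
            flat[c, :, :k] = pool[ofs : ofs + k].T
            ofs += k
    return out


def significance_intervals(
    recording: PopulationRecording | RateTensor,
    result: DecodingResult,
    n_shuffles: int = 100,
    alpha: float = 0.05,
    min_consecutive: int = 10,
    seed: int | None = None,
) -> DecodingResult:
    """Shuffle-null significance of a decoding time course.

    Re-runs the full decoding pipeline ``n_shuffles`` times on label-shuffled
    data; a bin is significant when the observed accuracy exceeds the
    (1 - alpha) order-statistic quantile of its null, and intervals are
    maximal runs of >= ``min_consecutive`` significant bins.  Returns a new
    DecodingResult carrying the null and the intervals.
    """
    tensor = _prepare(recording)
    counts = tensor.trial_counts()
    seed = result.seed if seed is None else seed
    shuffle_seeds = spawn_seeds(seed + 1_000_003, n_shuffles)
    null = np.empty((n_shuffles, result.accuracy.shape[0]))
    for k, s in enumerate(shuffle_seeds):
        rng = np.random.default_rng(s)
        shuffled = _shuffle_labels(tensor.trial_tensor, counts, rng)
        null[k] = _decode_accuracy(
            shuffled,
            counts,
            result.target,
            result.n_iterations,
            result.q_axes,
            result.reg,
            rng,
        )
    threshold = order_statistic_quantile(null, 1.0 - alpha)
    significant = result.accuracy > threshold
    intervals = find_runs(significant, min_consecutive, result.epoch_boundaries)
    from dataclasses import replace

    return replace(
        result,
        null_accuracies=null,
        null_threshold=threshold,
        significant_intervals=intervals,
    )


def min_population_analysis(
    recording: PopulationRecording,
    sizes: list[int],
    seed: int = 0,
    target: str = PARAMETER,
    n_iterations: int = 100,
    n_shuffles: int = 100,
    alpha: float = 0.05,
    min_consecutive: int = 10,
    q_axes: int = 1,
    reg="auto",
) -> dict[int, DecodingResult]:
    """Decoding + significance for neuron subsamples of several sizes.

    The full population is always included.  ``sizes`` equal to the full
    population size reuse the recording as-is, so the full-size entry is
    identical to decoding the recording directly with the same seed.
    """
    N = recording.n_neurons
    all_sizes = sorted(set(int(s) for s in sizes) | {N})
    if any(s > N for s in all_sizes):
        raise ValueError(f"requested size exceeds population size {N}")
    sub_seeds = dict(zip(all_sizes, spawn_seeds(seed + 7, len(all_sizes))))
    out: dict[int, DecodingResult] = {}
    for size in all_sizes:
        sub = recording if size == N else subsample_neurons(recording, size, sub_seeds[size])
        res = decode_timecourse(
            sub, target=target, n_iterations=n_iterations, q_axes=q_axes, reg=reg, seed=seed
        )
        out[size] = significance_intervals(
            sub, res, n_shuffles=n_shuffles, alpha=alpha, min_consecutive=min_consecutive
        )
    return out
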