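"""Trial-resolved recordings and the trial-averaged rate tensor.

Neurons are recorded separately (a pseudo-population): each neuron carries
its own list of trials labelled with a (parameter level, visual level)
condition and a binned firing-rate vector.  ``build_rate_tensor`` averages
trials within each condition cell into the ``N x S x V x T`` PSTH tensor
that the demixed-PCA machinery consumes, keeping the trial-resolved tensor
(with a validity mask — missing trials are masked, never imputed) for
cross-validated decoding.

Per-neuron centering weights every condition cell equally regardless of its
trial count, so unbalanced designs do not bias neuron means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .designs import TaskDesign


class Trial(NamedTuple):
    parameter_level: str
    visual_level: str
    rates: np.ndarray  # (T,) firing rate in spikes/s


@dataclass
class NeuronRecord:
    neuron_id: str
    trials: list[Trial]


@dataclass
class PopulationRecording:
    """A pseudo-population of separately recorded neurons under one design.

    ``min_trials``/``max_trials`` declare the allowed per-condition trial
    count range (7-15 for the recordings this pipeline models); ``validate``
    enforces them together with rate-vector length and non-negativity.
    """

    design: TaskDesign
    neurons: list[NeuronRecord]
    min_trials: int = 7
    max_trials: int = 15

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def trial_counts(self) -> np.ndarray:
        """Per-neuron, per-condition trial counts, shape (N, S, V)."""
        d = self.design
        counts = np.zeros((self.n_neurons, d.n_parameter_levels, d.n_visual_levels), int)
        for i, neuron in enumerate(self.neurons):
            for trial in neuron.trials:
                s = d.parameter_index(trial.parameter_level)
                v = d.visual_index(trial.visual_level)
                counts[i, s, v] += 1
        return counts

    def validate(self) -> None:
        d = self.design
        counts = self.trial_counts()
        for i, neuron in enumerate(self.neurons):
            for trial in neuron.trials:
                if trial.rates.shape != (d.n_bins,):
                    raise ValueError(
                        f"neuron {neuron.neuron_id}: rate vector of length "
                        f"{trial.rates.shape} != ({d.n_bins},)"
                    )
                if np.any(trial.rates < 0):
                    raise ValueError(
                        f"neuron {neuron.neuron_id}: negative firing rate"
                    )
            for s, p_level in enumerate(d.parameter_levels):
                for v, v_level in enumerate(d.visual_levels):
                    c = counts[i, s, v]
                    if c == 0:
                        raise ValueError(
                            f"neuron {neuron.neuron_id} has no trials for "
                            f"condition ({p_level}, {v_level})"
                        )
                    if not (self.min_trials <= c <= self.max_trials):
                        raise ValueError(
                            f"neuron {neuron.neuron_id}: {c} trials for "
                            f"({p_level}, {v_level}) outside declared range "
                            f"[{self.min_trials}, {self.max_trials}]"
                        )


@dataclass
class RateTensor:
    """Trial-averaged PSTH tensor with optional trial-resolved backing.

    Attributes
    ----------
    X : ndarray, shape (N, S, V, T)
        Trial-averaged firing rate (Hz), uncentered.
    neuron_means : ndarray, shape (N,)
        Per-neuron grand mean over (S, V, T) with equal condition weights;
        ``centered()`` removes it.
    trial_tensor : ndarray, shape (N, S, V, T, R), optional
        Trial-resolved rates; invalid slots are zero-filled and masked.
    trial_mask : ndarray, shape (N, S, V, R) of bool, optional
        Validity of each trial slot.
    """

    design: TaskDesign
    X: np.ndarray
    neuron_means: np.ndarray
    trial_tensor: np.ndarray | None = None
    trial_mask: np.ndarray | None = None
    neuron_ids: list[str] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.X.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.X.shape

    def centered(self) -> np.ndarray:
        """Per-neuron centered tensor (mean over S, V, T removed)."""
        return self.X - self.neuron_means[:, None, None, None]

    def trial_counts(self) -> np.ndarray | None:
        if self.trial_mask is None:
            return None
        return self.trial_mask.sum(axis=-1)


def build_rate_tensor(
    recording: PopulationRecording, keep_trials: bool = True
) -> RateTensor:
    """Average trials per condition cell into the (N, S, V, T) PSTH tensor.

    Raises if any neuron lacks a condition entirely (the neuron and the
    condition are named in the error).
    """
    d = recording.design
    N, S, V, T = (
        recording.n_neurons,
        d.n_parameter_levels,
        d.n_visual_levels,
        d.n_bins,
    )
    per_cell: list[list[list[list[np.ndarray]]]] = [
        [[[] for _ in range(V)] for _ in range(S)] for _ in range(N)
    ]
    for i, neuron in enumerate(recording.neurons):
        for trial in neuron.trials:
            s = d.parameter_index(trial.parameter_level)
            v = d.visual_index(trial.visual_level)
            rates = np.asarray(trial.rates, float)
            if rates.shape != (T,):
                raise ValueError(
                    f"neuron {neuron.neuron_id}: rate vector length "
                    f"{rates.shape[0]} != {T}"
                )
            per_cell[i][s][v].append(rates)

    counts = np.array(
        [[[len(per_cell[i][s][v]) for v in range(V)] for s in range(S)] for i in range(N)]
    )
    if np.any(counts == 0):
        i, s, v = map(int, np.argwhere(counts == 0)[0])
        raise ValueError(
            f"neuron {recording.neurons[i].neuron_id} has no trials for "
            f"condition ({d.parameter_levels[s]}, {d.visual_levels[v]})"
        )

    X = np.empty((N, S, V, T))
    trial_tensor = trial_mask = None
    if keep_trials:
        R = int(counts.max())
        trial_tensor = np.zeros((N, S, V, T, R))
        trial_mask = np.zeros((N, S, V, R), bool)
    for i in range(N):
        for s in range(S):
            for v in range(V):
                stack = np.stack(per_cell[i][s][v])
                X[i, s, v] = stack.mean(axis=0)
                if keep_trials:
                    r = stack.shape[0]
                    trial_tensor[i, s, v, :, :r] = stack.T
                    trial_mask[i, s, v, :r] = True

    neuron_means = X.mean(axis=(1, 2, 3))
    return RateTensor(
        design=d,
        X=X,
        neuron_means=neuron_means,
        trial_tensor=trial_tensor,
        trial_mask=trial_mask,
        neuron_ids=[n.neuron_id for n in recording.neurons],
    )


def subset_conditions(tensor: RateTensor, keep_parameters: Sequence[str]) -> RateTensor:
    """Restrict the tensor to a subset of parameter levels and re-center.

    Used for the symmetric 2 x 2 re-analysis that compares designs with
    different numbers of parameter levels on an equal footing.
    """
    sub_design = tensor.design.subset(keep_parameters)
    idx = [tensor.design.parameter_index(level) for level in sub_design.parameter_levels]
    X = tensor.X[:, idx]
    trial_tensor = None if tensor.trial_tensor is None else tensor.trial_tensor[:, idx]
    trial_mask = None if tensor.trial_mask is None else tensor.trial_mask[:, idx]
    return RateTensor(
        design=sub_design,
        X=X,
        neuron_means=X.mean(axis=(1, 2, 3)),
        trial_tensor=trial_tensor,
        trial_mask=trial_mask,
        neuron_ids=list(tensor.neuron_ids),
    )


def subsample_neurons(
    recording: PopulationRecording, n: int, seed: int
) -> PopulationRecording:
    """Uniform sample of ``n`` neurons without replacement; seeded."""
    if n > recording.n_neurons:
        raise ValueError(
            f"cannot sample {n} neurons from a population of {recording.n_neurons}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(recording.n_neurons, size=n, replace=False)
    return replace(recording, neurons=[recording.neurons[i] for i in idx])
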