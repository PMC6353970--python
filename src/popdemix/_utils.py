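"""Small shared helpers: run finding and seed derivation."""

from __future__ import annotations

from typing import Sequence

import numpy as np


def find_runs(
    mask: np.ndarray,
    min_length: int = 1,
    boundaries: Sequence[int] = (),
) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= ``min_length``, as half-open bins.

    ``boundaries`` are bin indices at which a new alignment epoch starts;
    runs are never allowed to span a boundary (the concatenated time axis is
    discontinuous there).
    """
    mask = np.asarray(mask, bool)
    cuts = [0, *sorted(set(int(b) for b in boundaries)), len(mask)]
    runs: list[tuple[int, int]] = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        seg = mask[lo:hi]
        if seg.size == 0:
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], seg.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start >= min_length:
                runs.append((lo + int(start), lo + int(stop)))
    return runs


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one integer seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) >> np.uint32(1)]


def order_statistic_quantile(values: np.ndarray, level: float) -> np.ndarray:
    """Upper quantile by order statistic: the ceil(level * n)-th sorted value.

    With 100 draws and level 0.95 this is the 95th order statistic.
    """
    values = np.sort(np.asarray(values, float), axis=0)
    n = values.shape[0]
    k = int(np.ceil(level * n)) - 1
    return values[max(k, 0)]
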