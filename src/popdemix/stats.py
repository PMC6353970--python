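"""Chi-squared comparison of variance percentages across and within tasks.

Each compared percentage is converted to a 2-column count row
``(round(p * base / 100), base - round(p * base / 100))`` — by default
percentage points out of 100 per group — and a Pearson chi-squared test of
homogeneity is run on the groups x 2 table.  The count base is an
interpretive choice: a variance percentage has no intrinsic sample size,
and "percentage points out of 100" is the convention this package adopts.
The base is exposed so users can probe sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency

__all__ = ["VarianceComparison", "chi2_compare"]


@dataclass
class VarianceComparison:
    labels: tuple[str, ...]
    percentages: tuple[float, ...]
    chi2: float
    dof: int
    p_value: float
    significant: bool
    alpha: float = 0.05
    base: int = 100


def chi2_compare(
    percentages: Sequence[float],
    base: int = 100,
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    yates: bool = False,
) -> VarianceComparison:
    """Pearson chi-squared on 2-3 variance percentages.

    Parameters
    ----------
    percentages : sequence of 2 or 3 values in [0, 100]
    base : int, default 100
        Counts per group; each percentage becomes ``round(p * base / 100)``
        "hits" out of ``base``.  Must be >= 10 (smaller bases make the
        counts degenerate).
    yates : bool, default False
        Continuity correction (off by default; 2x2 tables only).
    """
    values = tuple(float(p) for p in percentages)
    if not (2 <= len(values) <= 3):
        raise ValueError("compare 2 or 3 percentages")
    if any(not (0 <= p <= 100) for p in values):
        raise ValueError("percentages must lie in [0, 100]")
    if base < 10:
        raise ValueError("count base < 10 makes the table degenerate")
    hits = np.array([round(p * base / 100) for p in values])
    table = np.column_stack([hits, base - hits])
    if np.all(hits == hits[0]):
        # Identical proportions: chi2 = 0 exactly, p = 1 (avoid the
        # zero-column edge case when all hits are 0 or base).
        chi2, p, dof = 0.0, 1.0, len(values) - 1
    else:
        chi2, p, dof, _ = chi2_contingency(table, correction=yates)
    if labels is None:
        labels = tuple(f"group{i + 1}" for i in range(len(values)))
    return VarianceComparison(
        labels=tuple(labels),
        percentages=values,
        chi2=float(chi2),
        dof=int(dof),
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
        base=base,
    )
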