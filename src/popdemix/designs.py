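"""Factorial task designs for reach-to-grasp pseudo-population recordings.

A design is a task parameter factor (target position, wrist orientation or
grip type) crossed with a binary visual factor (movement in the light vs in
the dark), sampled on a fixed peri-movement time grid.  Time is binned at
``bin_width`` ms; each epoch window is half-open, bin ``t`` of an epoch
covering ``[start + t*bin_width, start + (t+1)*bin_width)`` ms relative to
that epoch's alignment event.  A design may concatenate two epochs aligned
on different events (object illumination and movement onset for grasping to
differently shaped objects); the bin index where the second epoch starts is
exposed as an epoch boundary and downstream interval logic never spans it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# Marginalization labels of the factorial ANOVA-style decomposition.
CONDITION_INDEPENDENT = "condition_independent"
PARAMETER = "parameter"
VISUAL = "visual"
INTERACTION = "interaction"
MARGINALIZATION_LABELS = (CONDITION_INDEPENDENT, PARAMETER, VISUAL, INTERACTION)

DEFAULT_WINDOW = (-4500, 2500)


@dataclass(frozen=True)
class TaskDesign:
    """A task-parameter × visual-condition design on a binned time grid.

    Parameters
    ----------
    name : str
        Design identifier, e.g. ``"reach_direction"``.
    parameter_levels : tuple of str
        Ordered task-parameter levels (S >= 2).
    visual_levels : tuple of str
        Ordered visual conditions; exactly two (light, dark).
    bin_width : int
        Bin width in milliseconds.
    epoch_windows : tuple of (int, int)
        One window per alignment event, each ``(start_ms, end_ms)`` relative
        to its event.  Window lengths must be multiples of ``bin_width``.
    alignment_events : tuple of str
        One or two event labels; epochs are concatenated along time in this
        order.
    """

    name: str
    parameter_levels: tuple[str, ...]
    visual_levels: tuple[str, str] = ("light", "dark")
    bin_width: int = 40
    epoch_windows: tuple[tuple[int, int], ...] = (DEFAULT_WINDOW,)
    alignment_events: tuple[str, ...] = ("movement_onset",)

    def __post_init__(self) -> None:
        object.__setattr__(self, "parameter_levels", tuple(self.parameter_levels))
        object.__setattr__(self, "visual_levels", tuple(self.visual_levels))
        object.__setattr__(
            self, "epoch_windows", tuple(tuple(w) for w in self.epoch_windows)
        )
        object.__setattr__(self, "alignment_events", tuple(self.alignment_events))
        if len(self.parameter_levels) < 2:
            raise ValueError("a design needs at least 2 task-parameter levels")
        if len(set(self.parameter_levels)) != len(self.parameter_levels):
            raise ValueError("parameter levels must be unique")
        if len(self.visual_levels) != 2:
            raise ValueError("exactly 2 visual conditions are supported")
        if len(self.alignment_events) not in (1, 2):
            raise ValueError("designs use 1 or 2 alignment events")
        if len(self.epoch_windows) != len(self.alignment_events):
            raise ValueError("one epoch window per alignment event is required")
        for start, end in self.epoch_windows:
            if end <= start:
                raise ValueError(f"empty epoch window ({start}, {end})")
            if (end - start) % self.bin_width:
                raise ValueError(
                    f"window ({start}, {end}) not divisible by bin width "
                    f"{self.bin_width}"
                )

    # -- shape ------------------------------------------------------------

    @property
    def n_parameter_levels(self) -> int:
        return len(self.parameter_levels)

    @property
    def n_visual_levels(self) -> int:
        return len(self.visual_levels)

    @property
    def epoch_n_bins(self) -> tuple[int, ...]:
        return tuple((e - s) // self.bin_width for s, e in self.epoch_windows)

    @property
    def n_bins(self) -> int:
        return sum(self.epoch_n_bins)

    @property
    def epoch_boundaries(self) -> tuple[int, ...]:
        """Bin indices at which a new epoch starts (first epoch excluded)."""
        bounds = np.cumsum(self.epoch_n_bins)[:-1]
        return tuple(int(b) for b in bounds)

    def bin_starts_ms(self) -> np.ndarray:
        """Start time (ms, relative to its epoch's event) of every bin."""
        parts = [
            start + self.bin_width * np.arange(nb)
            for (start, _), nb in zip(self.epoch_windows, self.epoch_n_bins)
        ]
        return np.concatenate(parts)

    def epoch_of_bin(self) -> np.ndarray:
        """Epoch index of every bin."""
        return np.repeat(np.arange(len(self.epoch_windows)), self.epoch_n_bins)

    # -- level lookups ----------------------------------------------------

    def parameter_index(self, level: str) -> int:
        try:
            return self.parameter_levels.index(level)
        except ValueError:
            raise KeyError(
                f"unknown parameter level {level!r}; design has "
                f"{self.parameter_levels}"
            ) from None

    def visual_index(self, level: str) -> int:
        try:
            return self.visual_levels.index(level)
        except ValueError:
            raise KeyError(
                f"unknown visual level {level!r}; design has {self.visual_levels}"
            ) from None

    def subset(self, keep_parameters: Sequence[str]) -> "TaskDesign":
        """Design restricted to a subset (>= 2) of parameter levels."""
        keep = tuple(keep_parameters)
        if len(keep) < 2:
            raise ValueError("at least 2 parameter levels must be kept")
        for level in keep:
            self.parameter_index(level)  # raises on unknown label
        return TaskDesign(
            name=self.name,
            parameter_levels=keep,
            visual_levels=self.visual_levels,
            bin_width=self.bin_width,
            epoch_windows=self.epoch_windows,
            alignment_events=self.alignment_events,
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "parameter_levels": list(self.parameter_levels),
            "visual_levels": list(self.visual_levels),
            "bin_width": self.bin_width,
            "epoch_windows": [list(w) for w in self.epoch_windows],
            "alignment_events": list(self.alignment_events),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskDesign":
        return cls(
            name=d["name"],
            parameter_levels=tuple(d["parameter_levels"]),
            visual_levels=tuple(d["visual_levels"]),
            bin_width=int(d.get("bin_width", 40)),
            epoch_windows=tuple(tuple(w) for w in d.get("epoch_windows", (DEFAULT_WINDOW,))),
            alignment_events=tuple(d.get("alignment_events", ("movement_onset",))),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TaskDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def reach_design() -> TaskDesign:
    """3 target positions × 2 visual conditions, aligned on movement onset."""
    return TaskDesign(
        name="reach_direction",
        parameter_levels=("left", "center", "right"),
    )


def wrist_design() -> TaskDesign:
    """2 wrist orientations × 2 visual conditions, aligned on movement onset."""
    return TaskDesign(
        name="wrist_orientation",
        parameter_levels=("horizontal", "vertical"),
    )


def grip_design() -> TaskDesign:
    """5 grip types × 2 visual conditions with dual alignment.

    Epochs are binned against object illumination and movement onset and
    concatenated with an explicit boundary; per-epoch windows are a package
    choice (the factorial structure, not the exact epoch extents, is what
    downstream analyses consume).
    """
    return TaskDesign(
        name="grip_type",
        parameter_levels=(
            "whole_hand",
            "finger",
            "hook",
            "primitive_precision",
            "advanced_precision",
        ),
        epoch_windows=((-1000, 1600), (-1600, 2400)),
        alignment_events=("object_illumination", "movement_onset"),
    )


DESIGN_FACTORIES = {
    "reach_direction": reach_design,
    "wrist_orientation": wrist_design,
    "grip_type": grip_design,
}
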