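"""Experiment-design description for promoter-reporter induction/recovery runs.

An experiment exposes a library of reporter strains to a sequence of heavy-metal
induction windows (4 h each by default), separated by recovery periods in plain
minimal media.  Fluorescence is imaged on a regular 10-minute grid; the analysis
selects a sparser 40-minute grid inside each window (6 induction points) and
after it (20 recovery points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

DEFAULT_METALS = ("zinc", "copper", "cadmium", "iron", "lead", "chromium")

RAW_SPACING_MIN = 10.0


@dataclass(frozen=True)
class ExperimentDesign:
    """Metals, induction-window boundaries and the sampling schedule.

    Parameters
    ----------
    metals
        Ordered condition labels, one per induction window.
    induction_starts
        Window start times in minutes, one per metal, strictly increasing.
    induction_length_min
        Duration of each induction window (240 min = 4 h by default).
    sampling_spacing_min
        Spacing of the selected analysis time points (40 min).
    n_induction_points
        Selected points per induction window (6; ``6 * 40`` exactly tiles the
        240-min window, the reference at the window start is not a column).
    n_recovery_points
        Selected points per recovery period (20), referenced to the window end.
    """

    metals: tuple[str, ...] = DEFAULT_METALS
    induction_starts: tuple[float, ...] = ()
    induction_length_min: float = 240.0
    sampling_spacing_min: float = 40.0
    n_induction_points: int = 6
    n_recovery_points: int = 20

    def __post_init__(self) -> None:
        if not self.metals:
            raise ValueError("design needs at least one metal")
        if len(set(self.metals)) != len(self.metals):
            raise ValueError("duplicate metal labels in design")
        if not self.induction_starts:
            # default layout: 60-min lead-in, windows separated by an 840-min
            # recovery span (> 20 * 40 min of recovery samples)
            period = self.induction_length_min + 840.0
            starts = tuple(60.0 + i * period for i in range(len(self.metals)))
            object.__setattr__(self, "induction_starts", starts)
        if len(self.induction_starts) != len(self.metals):
            raise ValueError("induction_starts must match metals")
        starts = np.asarray(self.induction_starts, dtype=float)
        if np.any(np.diff(starts) <= 0):
            raise ValueError("induction windows must be ordered in time")
        span = self.n_induction_points * self.sampling_spacing_min
        if span > self.induction_length_min:
            raise ValueError(
                "selected induction points do not fit in the induction window"
            )
        # windows (plus their recovery sampling span) must not overlap
        ends = starts + self.induction_length_min
        tail = self.n_recovery_points * self.sampling_spacing_min
        if np.any(starts[1:] < ends[:-1] + tail):
            raise ValueError("induction windows overlap the previous recovery span")

    # -- window geometry ---------------------------------------------------

    def window(self, metal: str) -> tuple[float, float]:
        i = self.metals.index(metal)
        start = self.induction_starts[i]
        return start, start + self.induction_length_min

    def induction_reference(self, metal: str) -> float:
        return self.window(metal)[0]

    def recovery_reference(self, metal: str) -> float:
        return self.window(metal)[1]

    def induction_times(self, metal: str) -> np.ndarray:
        """Selected induction time points: start + j*spacing, j = 1..n."""
        start, _ = self.window(metal)
        j = np.arange(1, self.n_induction_points + 1)
        return start + j * self.sampling_spacing_min

    def recovery_times(self, metal: str) -> np.ndarray:
        """Selected recovery time points: end + j*spacing, j = 1..n."""
        _, end = self.window(metal)
        j = np.arange(1, self.n_recovery_points + 1)
        return end + j * self.sampling_spacing_min

    def n_points(self, phase: str) -> int:
        if phase == "induction":
            return self.n_induction_points
        if phase == "recovery":
            return self.n_recovery_points
        raise ValueError(f"unknown phase {phase!r}")

    def condition_columns(self, phase: str) -> list[str]:
        """Column labels 'metal:j', metal-major then time-point index."""
        n = self.n_points(phase)
        return [f"{m}:{j}" for m in self.metals for j in range(1, n + 1)]

    def raw_grid(self, margin_min: float = 60.0) -> np.ndarray:
        """The full 10-min imaging grid covering every window and recovery span."""
        t0 = self.induction_starts[0] - margin_min
        t0 = min(t0, 0.0)
        last = self.recovery_times(self.metals[-1])[-1] + margin_min
        return np.arange(t0, last + RAW_SPACING_MIN / 2, RAW_SPACING_MIN)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "metals": list(self.metals),
            "induction_starts": [float(s) for s in self.induction_starts],
            "induction_length_min": self.induction_length_min,
            "sampling_spacing_min": self.sampling_spacing_min,
            "n_induction_points": self.n_induction_points,
            "n_recovery_points": self.n_recovery_points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        return cls(
            metals=tuple(d["metals"]),
            induction_starts=tuple(d.get("induction_starts", ())),
            induction_length_min=float(d.get("induction_length_min", 240.0)),
            sampling_spacing_min=float(d.get("sampling_spacing_min", 40.0)),
            n_induction_points=int(d.get("n_induction_points", 6)),
            n_recovery_points=int(d.get("n_recovery_points", 20)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
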