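"""In-memory containers for trap displacement records and ground-truth labels."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K


@dataclass
class Trace:
    """A uniformly sampled bead displacement record.

    Positions are in nm relative to the trap center; the force the motor
    ensemble works against is ``k_trap * position``.
    """

    positions: np.ndarray
    sample_rate_hz: float
    k_trap: float
    temperature_K: float = DEFAULT_TEMPERATURE_K
    condition: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 1 or self.positions.size < 1:
            raise ValueError("positions must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.k_trap <= 0:
            raise ValueError("k_trap must be positive")

    @property
    def n_samples(self) -> int:
        return self.positions.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.dt

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz


@dataclass
class TrueEvent:
    """One ground-truth binding event: a maximal interval with >= 1 head attached.

    ``transitions`` holds every kinetic transition inside the event as rows
    ``(time_s, kind, n_attached_after, mean_nm_after)`` with kind in
    {"attach", "detach"}; ``mean_nm_after`` is the quasi-static equilibrium
    bead position after the transition.
    """

    start_sample: int
    end_sample: int  # half-open [start, end)
    transitions: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample

    def duration_s(self, sample_rate_hz: float) -> float:
        return self.n_samples / sample_rate_hz


@dataclass
class GroundTruth:
    """Ground-truth annotations for a simulated trace."""

    events: list  # list[TrueEvent], sorted, non-overlapping

    def __post_init__(self) -> None:
        prev_end = -1
        for ev in self.events:
            if ev.end_sample <= ev.start_sample:
                raise ValueError("truth event must have end > start")
            if ev.start_sample < prev_end:
                raise ValueError("truth events must be sorted and non-overlapping")
            prev_end = ev.end_sample

    @property
    def n_events(self) -> int:
        return len(self.events)
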