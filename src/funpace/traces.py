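"""Core containers for electrophysiological signals.

A :class:`Trace` is a uniformly sampled signal (membrane potential in mV or
current density in pA/pF).  A :class:`Sweep` couples a response trace with the
voltage-protocol :class:`Epoch` list that elicited it, and a
:class:`Recording` groups sweeps that share sampling and units (one
experimental condition).

Conventions used throughout the package: time in ms, voltage in mV, current
density in pA/pF, inward current negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

VALID_UNITS = ("mV", "pA", "pA/pF")
VALID_MODES = ("whole_cell", "inside_out", "current_clamp")


class FormatError(ValueError):
    """Raised when a sweep-table file violates the on-disk format."""


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled signal.

    Parameters
    ----------
    t0 : float
        Start time in ms.
    dt : float
        Sampling interval in ms (> 0).
    samples : np.ndarray
        Ordered sample values; all finite, length >= 2.
    unit : str
        One of ``mV``, ``pA``, ``pA/pF``.
    label : str
        Free-text description.
    """

    t0: float
    dt: float
    samples: np.ndarray
    unit: str
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(self.samples.size)

    @property
    def duration(self) -> float:
        """Total duration in ms (n * dt)."""
        return self.dt * self.samples.size

    def with_samples(self, samples: np.ndarray, label: Optional[str] = None) -> "Trace":
        return replace(self, samples=np.asarray(samples, float),
                       label=self.label if label is None else label)


@dataclass(frozen=True)
class Epoch:
    """One segment of a voltage-clamp command protocol.

    Either a constant ``level`` (mV) or a linear ``ramp`` between two
    voltages (mV) over ``duration`` ms.
    """

    label: str
    duration: float
    level: Optional[float] = None
    ramp: Optional[tuple] = None  # (v_start, v_end) in mV

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("epoch duration must be > 0")
        if (self.level is None) == (self.ramp is None):
            raise ValueError("epoch needs exactly one of level or ramp")

    @property
    def ramp_rate(self) -> Optional[float]:
        """Ramp slope in mV/min, None for constant epochs."""
        if self.ramp is None:
            return None
        v0, v1 = self.ramp
        return (v1 - v0) / self.duration * 60000.0

    def command(self, dt: float) -> np.ndarray:
        """Command voltage sampled at dt over this epoch."""
        n = int(round(self.duration / dt))
        if self.level is not None:
            return np.full(n, float(self.level))
        v0, v1 = self.ramp
        # sample at segment start times; last sample sits one dt before v1
        return v0 + (v1 - v0) * np.arange(n) / n


@dataclass(frozen=True)
class Sweep:
    """One protocol repetition: epochs plus the recorded response."""

    epochs: Sequence[Epoch]
    response: Trace
    command: Optional[Trace] = None

    def __post_init__(self) -> None:
        total = sum(e.duration for e in self.epochs)
        if self.epochs and abs(total - self.response.duration) > self.response.dt:
            raise ValueError(
                f"epoch durations ({total} ms) do not match response "
                f"duration ({self.response.duration} ms)")

    def epoch_slice(self, index: int) -> slice:
        """Sample slice of the response covered by epoch ``index``."""
        dt = self.response.dt
        start = sum(e.duration for e in self.epochs[:index])
        stop = start + self.epochs[index].duration
        return slice(int(round(start / dt)), int(round(stop / dt)))

    def epoch_samples(self, index: int) -> np.ndarray:
        return self.response.samples[self.epoch_slice(index)]


@dataclass
class Recording:
    """A set of sweeps recorded under one condition."""

    sweeps: list
    condition: str = ""
    capacitance: Optional[float] = None  # pF
    mode: str = "whole_cell"
    temperature: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        if self.sweeps:
            dt0 = self.sweeps[0].response.dt
            unit0 = self.sweeps[0].response.unit
            for sw in self.sweeps:
                if abs(sw.response.dt - dt0) > 1e-12 * dt0:
                    raise ValueError("all sweeps must share dt")
                if sw.response.unit != unit0:
                    raise ValueError("all sweeps must share unit")

    @property
    def dt(self) -> float:
        return self.sweeps[0].response.dt

    @property
    def unit(self) -> str:
        return self.sweeps[0].response.unit
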