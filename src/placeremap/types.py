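"""Core domain containers shared across the analysis pipeline.

All spatial quantities are in centimetres, times in seconds, voltages in
microvolts, and firing rates in hertz unless a field name says otherwise.
Containers are thin, validated dataclasses around numpy arrays; heavier
tabular results use pandas DataFrames at the pipeline layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ParameterError",
    "InputError",
    "UndefinedMetricError",
    "ArenaSpec",
    "Trajectory",
    "SpikeTrain",
    "RateMap",
    "PlaceField",
    "LfpTrace",
    "Psd",
    "BandPower",
]


class ParameterError(ValueError):
    """A caller-supplied parameter violates a precondition."""


class InputError(ValueError):
    """Input data are malformed or insufficient for the requested operation."""


class UndefinedMetricError(ValueError):
    """The requested quantity is mathematically undefined for this input."""


@dataclass(frozen=True)
class ArenaSpec:
    """Rectangular open-field arena, origin at the south-west corner."""

    width: float = 80.0
    height: float = 80.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ParameterError("arena width and height must be positive")

    def contains(self, x: float, y: float) -> bool:
        return 0.0 < x < self.width and 0.0 < y < self.height


@dataclass(frozen=True)
class Trajectory:
    """Timestamped 2-D path of the animal: t strictly increasing, x/y in cm."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise InputError("t, x, y must be equal-length 1-D sequences")
        if t.size < 2:
            raise InputError("a trajectory needs at least two samples")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
            raise InputError("trajectory contains non-finite values")
        if np.any(np.diff(t) <= 0):
            raise InputError("trajectory timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (s) for one unit, optionally with a mean waveform (µV)."""

    times: np.ndarray
    waveform: np.ndarray | None = None
    waveform_fs: float | None = None
    unit_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1:
            raise InputError("spike times must be a 1-D sequence")
        if times.size and np.any(np.diff(times) < 0):
            raise InputError("spike times must be non-decreasing")
        object.__setattr__(self, "times", times)
        if self.waveform is not None:
            wf = np.asarray(self.waveform, dtype=float)
            if wf.ndim != 1 or wf.size < 2:
                raise InputError("waveform must be a 1-D sequence of samples")
            if self.waveform_fs is None or self.waveform_fs <= 0:
                raise ParameterError("waveform_fs must be positive when a waveform is given")
            object.__setattr__(self, "waveform", wf)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def clipped(self, t_start: float, t_stop: float) -> "SpikeTrain":
        """Return a copy restricted to [t_start, t_stop]."""
        keep = (self.times >= t_start) & (self.times <= t_stop)
        return SpikeTrain(self.times[keep], self.waveform, self.waveform_fs, self.unit_id)


@dataclass(frozen=True)
class RateMap:
    """Binned occupancy, spike counts, and firing rates over the arena.

    Grids are indexed ``[iy, ix]`` with bin centres at ``(i + 0.5) * bin_size``
    from the arena origin.  ``rate_raw`` and ``rate_smooth`` hold NaN on
    invalid bins (occupancy below the threshold used at construction).
    """

    bin_size: float
    occupancy: np.ndarray
    spike_count: np.ndarray
    rate_raw: np.ndarray
    rate_smooth: np.ndarray
    valid_mask: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        shapes = {
            self.occupancy.shape,
            self.spike_count.shape,
            self.rate_raw.shape,
            self.rate_smooth.shape,
            self.valid_mask.shape,
        }
        if len(shapes) != 1:
            raise InputError("rate-map grids must share one shape")
        if self.bin_size <= 0:
            raise ParameterError("bin_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.occupancy.shape

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x_centers, y_centers) in arena coordinates (cm)."""
        ny, nx = self.shape
        xc = self.origin[0] + (np.arange(nx) + 0.5) * self.bin_size
        yc = self.origin[1] + (np.arange(ny) + 0.5) * self.bin_size
        return xc, yc


@dataclass(frozen=True)
class PlaceField:
    """A detected place field: contiguous member bins plus summary stats."""

    member_bins: frozenset
    peak_rate: float
    com: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.member_bins:
            raise InputError("a place field must contain at least one bin")


@dataclass(frozen=True)
class LfpTrace:
    """A local-field-potential voltage trace (µV) at sampling rate fs (Hz)."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise InputError("LFP samples must be 1-D")
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class Psd:
    """One-sided power spectral density: freqs (Hz) vs power (µV²/Hz)."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise InputError("freqs and power must be equal-length 1-D arrays")
        if np.any(np.diff(f) <= 0) or f[0] < 0:
            raise InputError("frequency grid must be non-negative and increasing")
        if np.any(p < 0):
            raise InputError("PSD values must be non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class BandPower:
    """Absolute (µV²) and relative (fraction of total) power in one band."""

    band: tuple[float, float]
    absolute: float
    relative: float
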