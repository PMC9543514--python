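import numpy as np
import pytest

from placeremap.types import ArenaSpec, RateMap, SpikeTrain, Trajectory


@pytest.fixture
def arena() -> ArenaSpec:
    return ArenaSpec(80.0, 80.0)


def make_rate_map(
    rates: np.ndarray,
    occupancy: np.ndarray | None = None,
    bin_size: float = 2.5,
    valid: np.ndarray | None = None,
) -> RateMap:
    """Build a RateMap directly from a rate grid (smoothed == raw)."""
    rates = np.asarray(rates, dtype=float)
    if occupancy is None:
        occupancy = np.ones_like(rates)
    occupancy = np.asarray(occupancy, dtype=float)
    if valid is None:
        valid = occupancy > 0
    raw = np.where(valid, rates, np.nan)
    return RateMap(
        bin_size=bin_size,
        occupancy=occupancy,
        spike_count=rates * occupancy,
        rate_raw=raw,
        rate_smooth=raw.copy(),
        valid_mask=valid,
    )


def stationary_trajectory(x: float, y: float, duration: float, fs: float = 10.0) -> Trajectory:
    n = int(duration * fs)
    t = np.arange(n) / fs
    return Trajectory(t=t, x=np.full(n, x), y=np.full(n, y))


def uniform_train(n: int, duration: float) -> SpikeTrain:
    return SpikeTrain(np.linspace(0, duration, n, endpoint=False))
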