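"""Occupancy/rate maps, place-field detection, and spatial firing statistics.

The locational firing-rate map divides the arena into square bins, accumulates
dwell time (occupancy) and spike counts per bin, and converts them to firing
rates.  Bins visited for less than ``min_occupancy`` seconds are masked out of
every downstream statistic.  Smoothing is a mask-aware 3x3 boxcar: each bin is
replaced by the mean of its valid neighbours (itself included), so unvisited
bins neither leak zeros into the map nor receive a rate.

Spatial information follows the Skaggs bits-per-spike definition

    I = sum_i p_i (lambda_i / lambda_bar) log2(lambda_i / lambda_bar)

with p_i the occupancy probability of bin i, lambda_i its firing rate and
lambda_bar the occupancy-weighted mean rate.  Spatial coherence is the Pearson
correlation between the raw rate map and the map of 3x3 neighbour means
(centre bin excluded), a first-order measure of local smoothness of the firing
field.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import (
    ArenaSpec,
    InputError,
    ParameterError,
    PlaceField,
    RateMap,
    SpikeTrain,
    Trajectory,
    UndefinedMetricError,
)

__all__ = [
    "compute_rate_map",
    "detect_place_field",
    "field_com",
    "skaggs_information",
    "spatial_coherence",
    "mean_speed",
]

DEFAULT_BIN_SIZE = 2.5
DEFAULT_MIN_OCCUPANCY = 0.1


def _neighbor_mean(values: np.ndarray, valid: np.ndarray, include_center: bool) -> np.ndarray:
    """Mask-aware 3x3 window mean; NaN where the window holds no valid bin."""
    filled = np.where(valid, values, 0.0)
    kernel = np.ones((3, 3))
    if not include_center:
        kernel[1, 1] = 0.0
    total = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    count = ndimage.convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = total / count
    out[count == 0] = np.nan
    return out


def compute_rate_map(
    traj: Trajectory,
    spikes: SpikeTrain,
    bin_size: float = DEFAULT_BIN_SIZE,
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
    smoothing: str = "boxcar3",
    arena: ArenaSpec | None = None,
) -> RateMap:
    """Build the binned occupancy/spike-count/firing-rate map for one unit.

    Occupancy credits each position sample with its sampling interval (the
    final sample gets the median interval).  Each spike is assigned to the bin
    of the temporally nearest position sample.  Spikes outside the session are
    clipped off before binning.

    Parameters
    ----------
    traj
        The session trajectory.
    spikes
        Spike times for one unit; may be empty (yields an all-zero map).
    bin_size
        Square bin side in cm.
    min_occupancy
        Bins with less dwell time than this (s) are marked invalid.
    smoothing
        ``"boxcar3"`` (mask-aware 3x3 mean, the default) or ``"none"``.
    arena
        Arena extent; inferred from the trajectory bounding box when omitted.
    """
    if bin_size <= 0:
        raise ParameterError("bin_size must be positive")
    if smoothing not in ("boxcar3", "none"):
        raise ParameterError(f"unknown smoothing kernel {smoothing!r}")

    t, x, y = traj.t, traj.x, traj.y
    if arena is None:
        origin = (float(np.min(x)), float(np.min(y)))
        extent = (float(np.max(x)) - origin[0], float(np.max(y)) - origin[1])
        extent = (max(extent[0], bin_size), max(extent[1], bin_size))
    else:
        origin = (0.0, 0.0)
        extent = (arena.width, arena.height)

    nx = max(int(np.ceil(extent[0] / bin_size - 1e-9)), 1)
    ny = max(int(np.ceil(extent[1] / bin_size - 1e-9)), 1)

    dt = np.diff(t)
    dwell = np.append(dt, np.median(dt))

    ix = np.clip(((x - origin[0]) / bin_size).astype(int), 0, nx - 1)
    iy = np.clip(((y - origin[1]) / bin_size).astype(int), 0, ny - 1)

    occupancy = np.zeros((ny, nx))
    np.add.at(occupancy, (iy, ix), dwell)

    clipped = spikes.clipped(t[0], t[-1])
    spike_count = np.zeros((ny, nx))
    if clipped.n_spikes:
        # temporally nearest position sample for each spike
        idx = np.searchsorted(t, clipped.times)
        idx = np.clip(idx, 1, len(t) - 1)
        nearest = np.where(
            clipped.times - t[idx - 1] <= t[idx] - clipped.times, idx - 1, idx
        )
        np.add.at(spike_count, (iy[nearest], ix[nearest]), 1.0)

    valid = occupancy >= min_occupancy
    rate_raw = np.full((ny, nx), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_raw[valid] = spike_count[valid] / occupancy[valid]

    if smoothing == "boxcar3":
        rate_smooth = _neighbor_mean(rate_raw, valid, include_center=True)
        rate_smooth[~valid] = np.nan
    else:
        rate_smooth = rate_raw.copy()

    return RateMap(
        bin_size=bin_size,
        occupancy=occupancy,
        spike_count=spike_count,
        rate_raw=rate_raw,
        rate_smooth=rate_smooth,
        valid_mask=valid,
        origin=origin,
    )


def detect_place_field(
    rate_map: RateMap, peak_fraction: float = 0.2, min_bins: int = 9
) -> PlaceField | None:
    """Find the unit's place field on a smoothed rate map, if it has one.

    The field is the largest 4-connected component of valid bins whose
    smoothed rate reaches ``peak_fraction`` of the map's peak.  Area ties are
    broken by higher mean rate, then by lowest (row-major) bin index.  Returns
    None when no component reaches ``min_bins`` bins.
    """
    if not np.any(rate_map.valid_mask):
        raise InputError("rate map has no valid bins")
    if not (0 < peak_fraction <= 1):
        raise ParameterError("peak_fraction must be in (0, 1]")

    smooth = rate_map.rate_smooth
    finite = rate_map.valid_mask & np.isfinite(smooth)
    if not np.any(finite):
        raise InputError("rate map has no finite smoothed bins")
    peak = float(np.nanmax(smooth[finite]))
    if peak <= 0:
        return None  # a silent unit has no field
    candidate = finite & (smooth >= peak_fraction * peak)

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, n_comp = ndimage.label(candidate, structure=structure)
    if n_comp == 0:
        return None

    best = None
    for lab in range(1, n_comp + 1):
        mask = labels == lab
        area = int(mask.sum())
        mean_rate = float(smooth[mask].mean())
        first_index = int(np.flatnonzero(mask.ravel())[0])
        key = (area, mean_rate, -first_index)
        if best is None or key > best[0]:
            best = (key, mask)

    mask = best[1]
    if int(mask.sum()) < min_bins:
        return None
    member = frozenset((int(r), int(c)) for r, c in zip(*np.nonzero(mask)))
    field = PlaceField(
        member_bins=member,
        peak_rate=float(np.nanmax(smooth[mask])),
        com=(np.nan, np.nan),
    )
    com = field_com(rate_map, field)
    return PlaceField(member_bins=member, peak_rate=field.peak_rate, com=com)


def field_com(rate_map: RateMap, place_field: PlaceField) -> tuple[float, float]:
    """Rate-weighted centre of mass of the field's bins, in arena cm.

    Weights are the smoothed rates of the member bins only; bins outside the
    field do not contribute (the field, not the whole map, defines the COM).
    """
    xc, yc = rate_map.bin_centers()
    rows = np.array([r for r, _ in place_field.member_bins])
    cols = np.array([c for _, c in place_field.member_bins])
    weights = rate_map.rate_smooth[rows, cols]
    weights = np.where(np.isfinite(weights), weights, 0.0)
    total = weights.sum()
    if total <= 0:
        raise UndefinedMetricError("all member-bin rates are zero; COM undefined")
    return (
        float(np.sum(weights * xc[cols]) / total),
        float(np.sum(weights * yc[rows]) / total),
    )


def skaggs_information(rate_map: RateMap) -> float:
    """Spatial information content in bits per spike (Skaggs index).

    Valid bins with zero rate contribute nothing; the result is non-negative
    and zero iff the rate is uniform over visited space.
    """
    valid = rate_map.valid_mask & np.isfinite(rate_map.rate_raw)
    occ = rate_map.occupancy[valid]
    rates = rate_map.rate_raw[valid]
    total_occ = occ.sum()
    if total_occ <= 0:
        raise UndefinedMetricError("no occupancy; information undefined")
    p = occ / total_occ
    mean_rate = float(np.sum(p * rates))
    if mean_rate <= 0:
        raise UndefinedMetricError("zero mean rate; information undefined")
    ratio = rates / mean_rate
    pos = ratio > 0
    info = float(np.sum(p[pos] * ratio[pos] * np.log2(ratio[pos])))
    # flush eps-scale summation residue (a uniform map is exactly zero)
    return info if abs(info) > 1e-12 else 0.0


def spatial_coherence(rate_map: RateMap) -> float:
    """Pearson correlation between the raw map and its neighbour-mean map.

    The neighbour map averages the up-to-8 valid neighbours of each bin,
    centre excluded.  Requires at least 3 usable bins and non-degenerate
    variance in both maps.
    """
    valid = rate_map.valid_mask & np.isfinite(rate_map.rate_raw)
    neighbor = _neighbor_mean(rate_map.rate_raw, valid, include_center=False)
    usable = valid & np.isfinite(neighbor)
    if usable.sum() < 3:
        raise InputError("need at least 3 valid bins with valid neighbours")
    a = rate_map.rate_raw[usable]
    b = neighbor[usable]
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedMetricError("zero variance; coherence undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def mean_speed(traj: Trajectory) -> float:
    """Average running speed (cm/s): mean of per-step displacement / dt."""
    dt = np.diff(traj.t)
    if np.any(dt == 0):
        raise InputError("duplicate timestamps in trajectory")
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return float(np.mean(steps / dt))
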