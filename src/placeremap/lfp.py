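"""LFP spectral analysis: Welch periodograms and Simpson band integration.

Power spectral density is estimated with Welch's method (2 s Hamming windows,
50% overlap, per-segment linear detrend by default).  Band power is the
Simpson's-rule integral of the PSD over a band, with the band edges included
by linear interpolation onto the frequency grid.  Total power integrates
1.5-90 Hz — the range used to exclude very low and very high frequency noise —
and relative band power divides a band's absolute power by that total.

The canonical bands are delta 1.5-4 Hz, theta 5-11 Hz, and gamma 30-90 Hz.
Note the deliberate gaps (4-5 and 11-30 Hz): the three relative powers sum to
less than 1 by construction.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, signal

from .types import LfpTrace, ParameterError, Psd, BandPower, UndefinedMetricError

__all__ = [
    "BANDS",
    "TOTAL_RANGE",
    "welch_psd",
    "band_power",
    "total_power",
    "relative_band_powers",
]

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.5, 4.0),
    "theta": (5.0, 11.0),
    "gamma": (30.0, 90.0),
}
TOTAL_RANGE: tuple[float, float] = (1.5, 90.0)


def welch_psd(trace: LfpTrace, window_s: float = 2.0, overlap_frac: float = 0.5) -> Psd:
    """Welch power spectral density of an LFP trace.

    Parameters
    ----------
    trace
        Voltage samples (µV) with sampling rate ``fs``.
    window_s
        Segment length in seconds (Hamming window).
    overlap_frac
        Fractional overlap between segments, in [0, 1).
    """
    nperseg = int(round(window_s * trace.fs))
    if nperseg < 2 or nperseg > trace.samples.size:
        raise ParameterError("window must be >= 2 samples and fit inside the trace")
    if not (0 <= overlap_frac < 1):
        raise ParameterError("overlap_frac must be in [0, 1)")
    noverlap = int(round(overlap_frac * nperseg))
    freqs, power = signal.welch(
        trace.samples,
        fs=trace.fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="linear",
        scaling="density",
    )
    return Psd(freqs=freqs, power=power)


def band_power(psd: Psd, low: float, high: float) -> float:
    """Simpson's-rule integral of the PSD over [low, high] (µV²).

    Band edges are included by linear interpolation onto the frequency grid,
    so the integral covers the band exactly even when the edges fall between
    grid points.
    """
    if low >= high:
        raise ParameterError("band must satisfy low < high")
    f, p = psd.freqs, psd.power
    if low < f[0] or high > f[-1]:
        raise ParameterError(
            f"band [{low}, {high}] Hz outside PSD grid [{f[0]}, {f[-1]}] Hz"
        )
    inner = (f > low) & (f < high)
    grid = np.concatenate(([low], f[inner], [high]))
    vals = np.concatenate(([np.interp(low, f, p)], p[inner], [np.interp(high, f, p)]))
    # drop duplicated abscissae when an edge coincides with a grid point
    keep = np.concatenate(([True], np.diff(grid) > 0))
    grid, vals = grid[keep], vals[keep]
    if grid.size < 3:
        raise ParameterError("need at least 3 grid points inside the band")
    return float(integrate.simpson(vals, x=grid))


def total_power(
    psd: Psd,
    total_range: tuple[float, float] = TOTAL_RANGE,
    bands: dict[str, tuple[float, float]] | None = None,
) -> float:
    """Absolute power integrated over the total range (default 1.5-90 Hz).

    The integral is computed piecewise, split at the band edges that fall
    inside the range (delta/theta/gamma by default).  Splitting keeps the
    Simpson quadrature of each band consistent with its contribution to the
    total — composite Simpson weights a narrow spectral peak differently
    depending on where it falls in the integration grid, so without the
    split a sharply band-limited signal's relative power would depend on
    quadrature parity rather than on the spectrum.  Total power is then
    exactly the sum of the band powers and the gap powers.
    """
    if psd.freqs[0] > total_range[0] or psd.freqs[-1] < total_range[1]:
        raise ParameterError(
            f"PSD grid does not span the total range {total_range} Hz"
        )
    bands = BANDS if bands is None else bands
    lo, hi = total_range
    edges = sorted(
        {lo, hi}
        | {e for pair in bands.values() for e in pair if lo < e < hi}
    )
    return sum(band_power(psd, a, b) for a, b in zip(edges[:-1], edges[1:]))


def relative_band_powers(
    psd: Psd,
    bands: dict[str, tuple[float, float]] | None = None,
    total_range: tuple[float, float] = TOTAL_RANGE,
) -> dict[str, BandPower]:
    """Absolute and relative power for each named band.

    Relative power is the band's absolute power divided by the power over
    ``total_range``; with the default delta/theta/gamma bands the three
    fractions sum to < 1 because of the inter-band gaps.  Composite Simpson
    integrals over different partitions are not perfectly nested, so a
    fraction computed for a sharply band-limited signal can nominally exceed
    1 by a sliver of quadrature error; fractions are clamped into [0, 1].
    """
    bands = BANDS if bands is None else bands
    total = total_power(psd, total_range, bands)
    if total <= 0:
        raise UndefinedMetricError("total power is zero; relative power undefined")
    out: dict[str, BandPower] = {}
    for name, (low, high) in bands.items():
        absolute = band_power(psd, low, high)
        relative = float(np.clip(absolute / total, 0.0, 1.0))
        out[name] = BandPower(band=(low, high), absolute=absolute, relative=relative)
    return out
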