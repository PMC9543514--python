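"""Waveform and spike-train metrics, burst detection, and unit classification.

Units recorded extracellularly in the claustrum fall into two functional
groups: place cells (low mean rate, spatially selective firing) and bursting
cells (higher rate, spikes clustered into short high-frequency events, no
spatial tuning).  This module computes the per-unit metrics those labels rest
on and applies the classification rule:

* place cell — spatial information >= 0.5 bits/spike, spatial coherence
  >= 0.25, mean rate >= 0.25 Hz, and a detected place field;
* bursting cell — not a place cell, with burst propensity and mean rate above
  configurable thresholds;
* otherwise unclassified.

A burst is a maximal run of >= 2 spikes whose consecutive inter-spike
intervals are all <= 6 ms; two candidate bursts separated by less than the
50 ms minimum inter-burst interval merge into a single event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import InputError, ParameterError, SpikeTrain, UndefinedMetricError

__all__ = [
    "WaveformMetrics",
    "TrainMetrics",
    "BurstSummary",
    "UnitClass",
    "ClassifierConfig",
    "waveform_metrics",
    "train_metrics",
    "detect_bursts",
    "classify_unit",
]


@dataclass(frozen=True)
class WaveformMetrics:
    amplitude: float  # µV, first positive peak minus first negative peak
    width: float  # µs between the 25%-amplitude crossings around the main peak


@dataclass(frozen=True)
class TrainMetrics:
    mean_rate: float  # Hz
    mean_isi: float | None  # ms; None for fewer than 2 spikes
    n_spikes: int


@dataclass(frozen=True)
class BurstSummary:
    n_bursts: int
    spikes_per_burst: float | None  # mean; None when no bursts
    burst_durations: tuple[float, ...]  # ms
    propensity: float  # fraction of spikes inside bursts


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds for the place / bursting classification rule."""

    min_skaggs: float = 0.5  # bits/spike
    min_coherence: float = 0.25
    min_place_rate: float = 0.25  # Hz
    min_burst_propensity: float = 0.1
    min_burst_rate: float = 1.0  # Hz; bursting cells fire well above place cells


@dataclass(frozen=True)
class UnitClass:
    label: str  # "place" | "bursting" | "unclassified"
    criteria_report: dict = field(default_factory=dict)


def _local_extrema(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict-or-plateau local maxima and minima (interior)."""
    d = np.diff(w)
    maxima, minima = [], []
    for i in range(1, w.size - 1):
        left = w[i] - w[i - 1]
        right = w[i + 1] - w[i]
        if left > 0 and right < 0:
            maxima.append(i)
        elif left < 0 and right > 0:
            minima.append(i)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def waveform_metrics(waveform: np.ndarray, fs: float) -> WaveformMetrics:
    """Spike amplitude (µV) and width (µs) from a mean waveform.

    Amplitude is the value at the first (earliest) positive local peak minus
    the value at the first negative local peak; when a sign lacks a local
    extremum the global extreme of that sign stands in (a monophasic bump
    then has amplitude peak-minus-baseline).  Width is the time between the
    two crossings of the 25%-of-amplitude level that bracket the principal
    (largest-magnitude) peak, linearly interpolated between samples.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 8:
        raise InputError("waveform needs at least 8 samples")
    if fs <= 0:
        raise ParameterError("waveform sampling rate must be positive")

    maxima, minima = _local_extrema(w)
    pos_candidates = maxima[w[maxima] > 0] if maxima.size else maxima
    neg_candidates = minima[w[minima] < 0] if minima.size else minima
    if pos_candidates.size == 0 and neg_candidates.size == 0:
        raise UndefinedMetricError("monotone waveform has no extrema")

    pos_val = w[pos_candidates[0]] if pos_candidates.size else float(w.max())
    neg_val = w[neg_candidates[0]] if neg_candidates.size else float(w.min())
    amplitude = float(pos_val - neg_val)
    if amplitude <= 0:
        raise UndefinedMetricError("non-positive amplitude; degenerate waveform")

    # principal peak: largest |value| among the candidate extrema
    candidates = np.concatenate(
        [pos_candidates, neg_candidates]
        if pos_candidates.size and neg_candidates.size
        else [pos_candidates if pos_candidates.size else neg_candidates]
    )
    peak_idx = int(candidates[np.argmax(np.abs(w[candidates]))])
    peak_sign = 1.0 if w[peak_idx] >= 0 else -1.0
    signed = peak_sign * w  # principal peak now positive, level positive
    lvl = 0.25 * amplitude

    def cross_left() -> float:
        for i in range(peak_idx, 0, -1):
            if signed[i - 1] < lvl <= signed[i]:
                frac = (lvl - signed[i - 1]) / (signed[i] - signed[i - 1])
                return (i - 1) + frac
        return 0.0

    def cross_right() -> float:
        for i in range(peak_idx, signed.size - 1):
            if signed[i] >= lvl > signed[i + 1]:
                frac = (signed[i] - lvl) / (signed[i] - signed[i + 1])
                return i + frac
        return float(signed.size - 1)

    width_samples = cross_right() - cross_left()
    width_us = width_samples / fs * 1e6
    if width_us <= 0:
        raise UndefinedMetricError("could not bracket the principal peak")
    return WaveformMetrics(amplitude=amplitude, width=float(width_us))


def train_metrics(spikes: SpikeTrain, duration: float) -> TrainMetrics:
    """Mean firing rate (Hz) and mean inter-spike interval (ms)."""
    if duration <= 0:
        raise ParameterError("duration must be positive")
    n = spikes.n_spikes
    rate = n / duration
    if n >= 2:
        mean_isi = float(np.mean(np.diff(spikes.times)) * 1e3)
    else:
        mean_isi = None
    return TrainMetrics(mean_rate=float(rate), mean_isi=mean_isi, n_spikes=n)


def detect_bursts(
    spikes: SpikeTrain, max_intra_isi: float = 6.0, min_ibi: float = 50.0
) -> BurstSummary:
    """Detect burst events in a sorted spike train.

    Parameters are in milliseconds.  Candidate bursts are maximal runs of
    >= 2 spikes with all consecutive ISIs <= ``max_intra_isi``; candidates
    whose gap (end of one to start of the next) is below ``min_ibi`` are
    merged into one event, which then spans every spike between its first
    and last member.
    """
    times_ms = spikes.times * 1e3
    n = times_ms.size
    if n < 2:
        return BurstSummary(0, None, (), 0.0)

    isi = np.diff(times_ms)
    in_run = isi <= max_intra_isi

    # candidate runs as (start_spike, end_spike) inclusive indices
    runs: list[list[int]] = []
    i = 0
    while i < isi.size:
        if in_run[i]:
            j = i
            while j + 1 < isi.size and in_run[j + 1]:
                j += 1
            runs.append([i, j + 1])
            i = j + 1
        else:
            i += 1

    # merge candidates separated by < min_ibi
    merged: list[list[int]] = []
    for run in runs:
        if merged and times_ms[run[0]] - times_ms[merged[-1][1]] < min_ibi:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    if not merged:
        return BurstSummary(0, None, (), 0.0)

    sizes = [b - a + 1 for a, b in merged]
    durations = tuple(float(times_ms[b] - times_ms[a]) for a, b in merged)
    n_in_bursts = sum(sizes)
    return BurstSummary(
        n_bursts=len(merged),
        spikes_per_burst=float(np.mean(sizes)),
        burst_durations=durations,
        propensity=float(n_in_bursts / n),
    )


def classify_unit(
    skaggs: float | None,
    coherence: float | None,
    mean_rate: float,
    burst: BurstSummary,
    has_field: bool,
    config: ClassifierConfig = ClassifierConfig(),
) -> UnitClass:
    """Label a unit as place, bursting, or unclassified.

    The place criteria are conjunctive; a unit failing any of them is tested
    against the bursting profile (high propensity to burst and a mean rate
    above the bursting floor).
    """
    report = {
        "skaggs_ok": skaggs is not None and skaggs >= config.min_skaggs,
        "coherence_ok": coherence is not None and coherence >= config.min_coherence,
        "rate_ok": mean_rate >= config.min_place_rate,
        "has_field": bool(has_field),
        "burst_propensity_ok": burst.propensity >= config.min_burst_propensity,
        "burst_rate_ok": mean_rate >= config.min_burst_rate,
    }
    if report["skaggs_ok"] and report["coherence_ok"] and report["rate_ok"] and report["has_field"]:
        label = "place"
    elif report["burst_propensity_ok"] and report["burst_rate_ok"]:
        label = "bursting"
    else:
        label = "unclassified"
    return UnitClass(label=label, criteria_report=report)
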