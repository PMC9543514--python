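"""Orchestration of the full L1/D/L2 analysis and the paired statistics.

``run_ldl_analysis`` takes the three session bundles and produces, per unit
and session: the rate map, detected place field and its COM, Skaggs
information, spatial coherence, train/burst/waveform metrics, and the
place-vs-bursting classification.  Across sessions it computes the remapping
summary (L1DL2 angle and pairwise COM distances over units with a field in
all three sessions) and runs paired comparisons (L1 vs D, D vs L2, L1 vs L2)
for each unit-level metric.  LFP band powers are computed per channel and
compared the same way.

Paired tests follow the usual normality gate: a Shapiro-Wilk check on the
paired differences at alpha = 0.05 selects the paired t test when normality
is not rejected and the Wilcoxon signed-rank test otherwise; either test can
be forced.  No multiple-comparison correction is applied — the pairwise
p-values are reported unadjusted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import lfp as lfp_mod
from . import spatial, units as units_mod
from .remapping import ComTriplet, RemapSummary, remap_summary
from .synth import SessionData
from .types import InputError, UndefinedMetricError
from .units import ClassifierConfig

__all__ = [
    "AnalysisConfig",
    "PairedComparison",
    "LdlReport",
    "paired_comparison",
    "run_ldl_analysis",
    "write_report",
]

LABELS = ("L1", "D", "L2")
PAIRS = (("L1", "D"), ("D", "L2"), ("L1", "L2"))


@dataclass(frozen=True)
class AnalysisConfig:
    """Every tunable threshold of the analysis, with its default."""

    bin_size: float = 2.5  # cm
    min_occupancy: float = 0.1  # s
    smoothing: str = "boxcar3"
    peak_fraction: float = 0.2  # field threshold as a fraction of peak rate
    min_field_bins: int = 9
    classifier: ClassifierConfig = ClassifierConfig()
    welch_window_s: float = 2.0
    welch_overlap: float = 0.5
    normality_alpha: float = 0.05  # Shapiro gate for t vs Wilcoxon
    test_choice: str = "auto"  # "auto" | "t_paired" | "wilcoxon"


@dataclass(frozen=True)
class PairedComparison:
    name: str
    test: str  # "t_paired" | "wilcoxon" | "degenerate"
    statistic: float | None
    p_value: float | None
    n: int
    mean_a: float
    mean_b: float
    note: str = ""


@dataclass(frozen=True)
class LdlReport:
    unit_metrics: pd.DataFrame  # one row per (session, unit)
    remap: RemapSummary | None
    remap_excluded: tuple[tuple[str, str], ...]
    band_powers: pd.DataFrame  # one row per (session, channel, band)
    paired_tests: tuple[PairedComparison, ...]
    config: AnalysisConfig


def paired_comparison(
    pairs: list[tuple[float, float]],
    test: str = "auto",
    name: str = "",
    normality_alpha: float = 0.05,
) -> PairedComparison:
    """Two-tailed paired comparison of matched samples.

    ``test='auto'`` applies the Shapiro-Wilk normality gate on the paired
    differences; all-zero differences give the conventional t = 0, p = 1,
    while constant non-zero differences are flagged as degenerate (the t
    statistic has zero variance in the denominator).
    """
    if len(pairs) < 2:
        raise InputError("need at least 2 complete pairs")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    diff = a - b
    n = diff.size

    if np.all(diff == 0):
        return PairedComparison(name, "t_paired", 0.0, 1.0, n, float(a.mean()), float(b.mean()),
                                note="all differences zero")
    if np.std(diff, ddof=1) == 0:
        return PairedComparison(name, "degenerate", None, None, n, float(a.mean()),
                                float(b.mean()), note="constant non-zero differences")

    chosen = test
    if test == "auto":
        if n >= 3:
            p_norm = stats.shapiro(diff).pvalue
            chosen = "t_paired" if p_norm >= normality_alpha else "wilcoxon"
        else:
            chosen = "t_paired"
    if chosen == "t_paired":
        res = stats.ttest_rel(a, b)
        return PairedComparison(name, "t_paired", float(res.statistic), float(res.pvalue),
                                n, float(a.mean()), float(b.mean()))
    if chosen == "wilcoxon":
        res = stats.wilcoxon(a, b, zero_method="wilcox", method="auto")
        return PairedComparison(name, "wilcoxon", float(res.statistic), float(res.pvalue),
                                n, float(a.mean()), float(b.mean()))
    raise InputError(f"unknown test {test!r}")


UNIT_COLUMNS = [
    "session", "unit_id", "n_spikes", "rate_hz", "isi_ms", "skaggs", "coherence",
    "has_field", "com_x", "com_y", "field_peak_hz", "n_bursts", "burst_propensity",
    "spikes_per_burst", "amplitude_uv", "width_us", "class",
]
BAND_COLUMNS = [
    "session", "channel", "band", "low_hz", "high_hz", "absolute_uv2", "relative",
    "total_uv2",
]


def _analyse_unit(
    session: SessionData, label: str, uid: str, config: AnalysisConfig
) -> dict:
    train = session.spikes[uid]
    rate_map = spatial.compute_rate_map(
        session.trajectory,
        train,
        bin_size=config.bin_size,
        min_occupancy=config.min_occupancy,
        smoothing=config.smoothing,
        arena=session.arena,
    )
    row: dict = {
        "session": label,
        "unit_id": uid,
        "n_spikes": train.n_spikes,
    }
    tm = units_mod.train_metrics(train, session.duration)
    row["rate_hz"] = tm.mean_rate
    row["isi_ms"] = tm.mean_isi

    try:
        row["skaggs"] = spatial.skaggs_information(rate_map)
    except Exception:
        row["skaggs"] = None
    try:
        row["coherence"] = spatial.spatial_coherence(rate_map)
    except Exception:
        row["coherence"] = None

    try:
        place_field = spatial.detect_place_field(
            rate_map, config.peak_fraction, config.min_field_bins
        )
    except (InputError, UndefinedMetricError):
        place_field = None
    row["has_field"] = place_field is not None
    row["com_x"] = place_field.com[0] if place_field else None
    row["com_y"] = place_field.com[1] if place_field else None
    row["field_peak_hz"] = place_field.peak_rate if place_field else None

    burst = units_mod.detect_bursts(train)
    row["n_bursts"] = burst.n_bursts
    row["burst_propensity"] = burst.propensity
    row["spikes_per_burst"] = burst.spikes_per_burst

    if train.waveform is not None:
        try:
            wf = units_mod.waveform_metrics(train.waveform, train.waveform_fs)
            row["amplitude_uv"] = wf.amplitude
            row["width_us"] = wf.width
        except Exception:
            row["amplitude_uv"] = None
            row["width_us"] = None
    else:
        row["amplitude_uv"] = None
        row["width_us"] = None

    label = units_mod.classify_unit(
        row["skaggs"],
        row["coherence"],
        tm.mean_rate,
        burst,
        row["has_field"],
        config.classifier,
    )
    row["class"] = label.label
    return row


def run_ldl_analysis(
    sessions: dict[str, SessionData], config: AnalysisConfig = AnalysisConfig()
) -> LdlReport:
    """Run the full three-session analysis on loaded bundles."""
    missing = [lab for lab in LABELS if lab not in sessions]
    if missing:
        raise InputError(f"missing sessions: {missing}")

    unit_ids = sorted(
        set.intersection(*(set(sessions[lab].spikes) for lab in LABELS))
        | set.union(*(set(sessions[lab].spikes) for lab in LABELS))
    )

    rows = []
    for lab in LABELS:
        for uid in sorted(sessions[lab].spikes):
            rows.append(_analyse_unit(sessions[lab], lab, uid, config))
    unit_metrics = pd.DataFrame(rows, columns=UNIT_COLUMNS)

    # remapping over units with a field in all three sessions
    triplets: list[ComTriplet] = []
    excluded: list[tuple[str, str]] = []
    shared = set.intersection(*(set(sessions[lab].spikes) for lab in LABELS))
    by_key = {(r["session"], r["unit_id"]): r for r in rows}
    for uid in sorted(shared):
        if not any(by_key[(lab, uid)]["class"] == "place" for lab in LABELS):
            excluded.append((uid, "not a place cell in any session"))
            continue
        coms = {}
        ok = True
        for lab in LABELS:
            r = by_key[(lab, uid)]
            if not r["has_field"]:
                excluded.append((uid, f"no field in {lab}"))
                ok = False
                break
            coms[lab] = (r["com_x"], r["com_y"])
        if ok:
            triplets.append(ComTriplet(uid, coms["L1"], coms["D"], coms["L2"]))
    for uid in sorted(set(unit_ids) - shared):
        excluded.append((uid, "not recorded in all three sessions"))

    remap = remap_summary(triplets) if triplets else None
    if remap is not None:
        excluded.extend(remap.excluded)

    # LFP band powers
    band_rows = []
    for lab in LABELS:
        for ch, trace in sorted(sessions[lab].lfp.items()):
            psd = lfp_mod.welch_psd(trace, config.welch_window_s, config.welch_overlap)
            total = lfp_mod.total_power(psd)
            for band_name, bp in lfp_mod.relative_band_powers(psd).items():
                band_rows.append(
                    {
                        "session": lab,
                        "channel": ch,
                        "band": band_name,
                        "low_hz": bp.band[0],
                        "high_hz": bp.band[1],
                        "absolute_uv2": bp.absolute,
                        "relative": bp.relative,
                        "total_uv2": total,
                    }
                )
    band_powers = pd.DataFrame(band_rows, columns=BAND_COLUMNS)

    # paired comparisons across conditions
    tests: list[PairedComparison] = []
    metric_cols = ("rate_hz", "skaggs", "coherence", "amplitude_uv", "width_us")
    for metric in metric_cols:
        for lab_a, lab_b in PAIRS:
            pairs = []
            for uid in sorted(shared):
                va = by_key[(lab_a, uid)].get(metric)
                vb = by_key[(lab_b, uid)].get(metric)
                if (
                    va is not None
                    and vb is not None
                    and np.isfinite(va)
                    and np.isfinite(vb)
                ):
                    pairs.append((float(va), float(vb)))
            if len(pairs) >= 2:
                tests.append(
                    paired_comparison(
                        pairs,
                        config.test_choice,
                        name=f"{metric}:{lab_a}_vs_{lab_b}",
                        normality_alpha=config.normality_alpha,
                    )
                )
    if not band_powers.empty:
        for band_name in ("delta", "theta", "gamma"):
            for lab_a, lab_b in PAIRS:
                sub_a = band_powers.query("session == @lab_a and band == @band_name")
                sub_b = band_powers.query("session == @lab_b and band == @band_name")
                merged = sub_a.merge(sub_b, on="channel", suffixes=("_a", "_b"))
                pairs = list(zip(merged["relative_a"], merged["relative_b"]))
                if len(pairs) >= 2:
                    tests.append(
                        paired_comparison(
                            pairs,
                            config.test_choice,
                            name=f"rel_{band_name}:{lab_a}_vs_{lab_b}",
                            normality_alpha=config.normality_alpha,
                        )
                    )

    return LdlReport(
        unit_metrics=unit_metrics,
        remap=remap,
        remap_excluded=tuple(excluded),
        band_powers=band_powers,
        paired_tests=tuple(tests),
        config=config,
    )


_FLOAT_FMT = "%.6f"


def write_report(report: LdlReport, out_dir: str | Path) -> Path:
    """Write the report as CSV tables plus a JSON summary.

    Output is deterministic: identical reports produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report.unit_metrics.sort_values(["session", "unit_id"]).to_csv(
        out / "unit_metrics.csv", index=False, float_format=_FLOAT_FMT
    )
    report.band_powers.to_csv(
        out / "band_powers.csv", index=False, float_format=_FLOAT_FMT
    )

    remap_rows = []
    if report.remap is not None:
        for r in report.remap.per_unit:
            remap_rows.append(
                {
                    "unit_id": r.unit_id,
                    "angle_deg": r.angle,
                    "d_L1D_cm": r.d_l1d,
                    "d_L1L2_cm": r.d_l1l2,
                    "d_DL2_cm": r.d_dl2,
                }
            )
    pd.DataFrame(
        remap_rows, columns=["unit_id", "angle_deg", "d_L1D_cm", "d_L1L2_cm", "d_DL2_cm"]
    ).to_csv(out / "remapping.csv", index=False, float_format=_FLOAT_FMT)

    test_rows = [
        {
            "name": t.name,
            "test": t.test,
            "statistic": t.statistic,
            "p_value": t.p_value,
            "n": t.n,
            "mean_a": t.mean_a,
            "mean_b": t.mean_b,
            "note": t.note,
        }
        for t in report.paired_tests
    ]
    pd.DataFrame(
        test_rows,
        columns=["name", "test", "statistic", "p_value", "n", "mean_a", "mean_b", "note"],
    ).to_csv(out / "paired_tests.csv", index=False, float_format=_FLOAT_FMT)

    summary = {
        "n_units": int(report.unit_metrics["unit_id"].nunique()) if not report.unit_metrics.empty else 0,
        "excluded_from_remap": [list(e) for e in report.remap_excluded],
        "remap": None,
        "config": {
            "bin_size": report.config.bin_size,
            "min_occupancy": report.config.min_occupancy,
            "smoothing": report.config.smoothing,
            "peak_fraction": report.config.peak_fraction,
            "min_field_bins": report.config.min_field_bins,
            "welch_window_s": report.config.welch_window_s,
            "welch_overlap": report.config.welch_overlap,
            "normality_alpha": report.config.normality_alpha,
            "test_choice": report.config.test_choice,
            "classifier": {
                "min_skaggs": report.config.classifier.min_skaggs,
                "min_coherence": report.config.classifier.min_coherence,
                "min_place_rate": report.config.classifier.min_place_rate,
                "min_burst_propensity": report.config.classifier.min_burst_propensity,
                "min_burst_rate": report.config.classifier.min_burst_rate,
            },
        },
    }
    if report.remap is not None:
        summary["remap"] = {
            "n": report.remap.n,
            "mean_angle_deg": report.remap.mean_angle,
            "sem_angle_deg": report.remap.sem_angle,
            "mean_d_L1D_cm": report.remap.mean_d_l1d,
            "sem_d_L1D_cm": report.remap.sem_d_l1d,
            "mean_d_L1L2_cm": report.remap.mean_d_l1l2,
            "sem_d_L1L2_cm": report.remap.sem_d_l1l2,
            "mean_d_DL2_cm": report.remap.mean_d_dl2,
            "sem_d_DL2_cm": report.remap.sem_d_dl2,
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
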