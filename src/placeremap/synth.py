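"""Seeded synthetic data emulating a light/dark/light (L1/D/L2) foraging
experiment: open-field trajectories, place-cell and bursting-cell spike
trains, and band-structured LFP traces.

The generator encodes the study conditions as defaults — an 80 x 80 cm square
arena, three 10-minute sessions, ~10 cm/s running speed, place cells whose
session mean rate is ~0.35 Hz in light and scaled by 0.65 in darkness,
bursting cells near 3 Hz, a dark-session field displacement of 12.75 cm
forming a ~50 degree angle with the two light-session fields, and LFP with a
configurable delta/theta/gamma composition.

Every operation is a pure function of its arguments and an integer seed.

Models
------
* Trajectory: constant-interval samples of a smoothed random walk — speed is
  an Ornstein-Uhlenbeck process around the target mean (clipped at 0),
  heading is Brownian, and the unbounded path is folded into the arena by
  reflection.
* Place cell: inhomogeneous Poisson spikes by thinning, with rate field
  ``lambda(x, y) = scale * (baseline + (peak - baseline) * exp(-d^2 / 2 sigma^2))``
  around the field centre of mass.
* Bursting cell: burst events from a renewal process with a hard minimum
  inter-burst interval; each event carries ``2 + Poisson(mean - 2)`` spikes
  at jittered intra-burst intervals.
* LFP: spectrally shaped Gaussian noise — band-passed white noise per band
  scaled so each band's power is the requested fraction of total 1.5-90 Hz
  power, on top of a broadband noise floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

from .lfp import TOTAL_RANGE
from .types import ArenaSpec, LfpTrace, ParameterError, SpikeTrain, Trajectory

__all__ = [
    "PlaceCellSpec",
    "BurstCellSpec",
    "LfpSpec",
    "SessionPlan",
    "ExperimentConfig",
    "SessionData",
    "LdlExperiment",
    "LIGHT_BAND_PROFILE",
    "DARK_BAND_PROFILE",
    "simulate_trajectory",
    "simulate_place_cell",
    "simulate_bursting_cell",
    "simulate_lfp",
    "generate_ldl_experiment",
]

# relative delta/theta/gamma power profiles for light and dark sessions,
# matching the claustral values the simulator is meant to emulate
LIGHT_BAND_PROFILE: tuple[tuple[float, float, float], ...] = (
    (1.5, 4.0, 0.312),
    (5.0, 11.0, 0.274),
    (30.0, 90.0, 0.099),
)
DARK_BAND_PROFILE: tuple[tuple[float, float, float], ...] = (
    (1.5, 4.0, 0.280),
    (5.0, 11.0, 0.314),
    (30.0, 90.0, 0.099),
)


@dataclass(frozen=True)
class PlaceCellSpec:
    """Isotropic Gaussian place field.

    The defaults are calibrated so the realised session mean rate on the
    default trajectory is ~0.35 Hz in light (and 0.65 x that, ~0.23 Hz, in
    darkness): the uniform-coverage estimate is baseline + (peak - baseline)
    * 2 pi sigma^2 / area, and the residual occupancy non-uniformity of the
    simulated paths brings peak 3.3 Hz to a measured ~0.35 Hz.
    """

    peak_rate: float = 3.3  # Hz at the field centre
    field_sigma: float = 10.0  # cm
    baseline_rate: float = 0.05  # Hz away from the field

    def __post_init__(self) -> None:
        if not (self.peak_rate >= self.baseline_rate >= 0):
            raise ParameterError("need peak_rate >= baseline_rate >= 0")
        if self.field_sigma <= 0:
            raise ParameterError("field_sigma must be positive")


@dataclass(frozen=True)
class BurstCellSpec:
    mean_rate: float = 3.0  # Hz overall
    intra_burst_isi: float = 4.0  # ms, jittered per spike
    spikes_per_burst_mean: float = 3.0  # events carry 2 + Poisson(mean - 2)
    inter_burst_interval: float = 50.0  # ms hard minimum between events

    def __post_init__(self) -> None:
        if not (0 < self.intra_burst_isi < 6.0):
            raise ParameterError("intra_burst_isi must lie in (0, 6) ms")
        if self.inter_burst_interval < 50.0:
            raise ParameterError("inter_burst_interval must be >= 50 ms")
        if self.spikes_per_burst_mean < 2.0:
            raise ParameterError("spikes_per_burst_mean must be >= 2")
        if self.mean_rate <= 0:
            raise ParameterError("mean_rate must be positive")


@dataclass(frozen=True)
class LfpSpec:
    fs: float = 250.0  # Hz
    band_components: tuple[tuple[float, float, float], ...] = LIGHT_BAND_PROFILE
    noise_floor: float = 20.0  # µV rms of the broadband background

    def __post_init__(self) -> None:
        total_rel = sum(c[2] for c in self.band_components)
        if any(c[2] < 0 for c in self.band_components) or total_rel > 1 + 1e-9:
            raise ParameterError("relative powers must be >= 0 and sum to <= 1")
        highest = max((c[1] for c in self.band_components), default=0.0)
        if self.fs < 2 * highest:
            raise ParameterError("sampling rate below Nyquist for the highest band")


@dataclass(frozen=True)
class SessionPlan:
    label: str  # L1 | D | L2
    duration: float  # s
    rate_scale: float  # multiplier on place-cell firing
    lfp_bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.label not in ("L1", "D", "L2"):
            raise ParameterError("session label must be one of L1, D, L2")
        if self.duration <= 0 or self.rate_scale < 0:
            raise ParameterError("duration must be > 0 and rate_scale >= 0")


@dataclass(frozen=True)
class ExperimentConfig:
    """Ground-truth configuration of a simulated L1/D/L2 experiment."""

    arena: ArenaSpec = ArenaSpec()
    n_place_cells: int = 20
    n_burst_cells: int = 0
    duration: float = 600.0  # s per session
    sample_rate: float = 50.0  # Hz position tracking
    mean_speed: float = 10.0  # cm/s
    angle_deg: float = 50.0  # true L1DL2 angle
    shift_cm: float = 12.75  # true |L1 - D| displacement
    dark_rate_scale: float = 0.65  # 0.23 / 0.35 light-to-dark rate drop
    place_spec: PlaceCellSpec = PlaceCellSpec()
    burst_spec: BurstCellSpec = BurstCellSpec()
    lfp_fs: float = 250.0
    lfp_noise_floor: float = 20.0
    n_lfp_channels: int = 1
    field_margin: float = 6.0  # cm clearance kept between any true COM and walls


@dataclass(frozen=True)
class SessionData:
    """Everything recorded in one session of the simulated experiment."""

    label: str
    arena: ArenaSpec
    duration: float
    trajectory: Trajectory
    spikes: dict[str, SpikeTrain]
    lfp: dict[str, LfpTrace]


@dataclass(frozen=True)
class LdlExperiment:
    config: ExperimentConfig
    seed: int
    sessions: dict[str, SessionData]
    true_coms: dict[str, dict[str, tuple[float, float]]]  # unit -> label -> COM
    unit_kinds: dict[str, str]  # unit -> "place" | "bursting"


def simulate_trajectory(
    arena: ArenaSpec,
    duration: float,
    mean_speed: float,
    sample_rate: float,
    seed: int,
    speed_sd: float = 3.0,
    speed_tau: float = 1.0,
    heading_diffusion: float = 1.0,
) -> Trajectory:
    """Simulate open-field foraging as a smoothed random walk.

    Speed follows an Ornstein-Uhlenbeck process (mean ``mean_speed``, sd
    ``speed_sd``, relaxation time ``speed_tau`` s) clipped at zero; heading
    diffuses with coefficient ``heading_diffusion`` rad/sqrt(s).  The
    unconstrained path is folded into the arena by reflection, which
    preserves step lengths except at the fold itself.

    The heading-diffusion default keeps paths straight enough to mix over
    the arena many times within a 10-minute session, giving the roughly
    uniform occupancy characteristic of pellet-chasing foraging.
    """
    if duration <= 0 or mean_speed <= 0 or sample_rate <= 0:
        raise ParameterError("duration, mean_speed and sample_rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    dt = 1.0 / sample_rate
    t = np.arange(n) * dt

    # AR(1) discretisation of the OU speed process
    a = math.exp(-dt / speed_tau)
    innov = rng.standard_normal(n) * speed_sd * math.sqrt(1 - a * a)
    innov[0] = rng.standard_normal() * speed_sd  # stationary start
    dev = sp_signal.lfilter([1.0], [1.0, -a], innov)
    speed = np.clip(mean_speed + dev, 0.0, None)

    theta = rng.uniform(0, 2 * math.pi) + np.cumsum(
        rng.standard_normal(n) * heading_diffusion * math.sqrt(dt)
    )
    start = np.array(
        [rng.uniform(0.25, 0.75) * arena.width, rng.uniform(0.25, 0.75) * arena.height]
    )
    x = start[0] + np.cumsum(speed * dt * np.cos(theta))
    y = start[1] + np.cumsum(speed * dt * np.sin(theta))
    x[0], y[0] = start  # first sample at the start position

    def fold(v: np.ndarray, width: float) -> np.ndarray:
        period = 2 * width
        vm = np.mod(v, period)
        folded = np.where(vm > width, period - vm, vm)
        eps = 1e-6 * width
        return np.clip(folded, eps, width - eps)

    return Trajectory(t=t, x=fold(x, arena.width), y=fold(y, arena.height))


def _rate_at(
    traj: Trajectory,
    times: np.ndarray,
    spec: PlaceCellSpec,
    com: tuple[float, float],
    rate_scale: float,
) -> np.ndarray:
    x = np.interp(times, traj.t, traj.x)
    y = np.interp(times, traj.t, traj.y)
    d2 = (x - com[0]) ** 2 + (y - com[1]) ** 2
    bump = np.exp(-d2 / (2 * spec.field_sigma**2))
    return rate_scale * (spec.baseline_rate + (spec.peak_rate - spec.baseline_rate) * bump)


def simulate_place_cell(
    traj: Trajectory,
    spec: PlaceCellSpec,
    field_com: tuple[float, float],
    rate_scale: float,
    seed: int,
    arena: ArenaSpec | None = None,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes by thinning against the place field.

    A homogeneous Poisson candidate train at the peak rate is thinned with
    probability ``lambda(x(t), y(t)) / lambda_max`` using the position
    linearly interpolated at each candidate time.
    """
    if rate_scale < 0:
        raise ParameterError("rate_scale must be >= 0")
    if arena is not None and not arena.contains(*field_com):
        raise ParameterError(f"field COM {field_com} outside arena")
    rng = np.random.default_rng(seed)
    lam_max = rate_scale * spec.peak_rate
    t0, t1 = float(traj.t[0]), float(traj.t[-1])
    if lam_max <= 0:
        return SpikeTrain(np.empty(0))
    n_cand = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n_cand))
    lam = _rate_at(traj, cand, spec, field_com, rate_scale)
    keep = rng.uniform(0, lam_max, n_cand) < lam
    return SpikeTrain(cand[keep])


def simulate_bursting_cell(duration: float, spec: BurstCellSpec, seed: int) -> SpikeTrain:
    """Spike train of a bursting (non-spatial) unit.

    Burst events arrive as a renewal process whose inter-event gap is the
    minimum inter-burst interval plus an exponential tail sized so the
    overall firing rate matches ``spec.mean_rate``; each event carries
    ``2 + Poisson(mean - 2)`` spikes at jittered intra-burst intervals
    (0.7-1.1 times ``intra_burst_isi``, always below the 6 ms criterion).
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    rng = np.random.default_rng(seed)
    m = spec.spikes_per_burst_mean
    mean_burst_dur = (m - 1) * spec.intra_burst_isi * 0.9 / 1e3  # s
    ibi_s = spec.inter_burst_interval / 1e3
    mean_gap_target = m / spec.mean_rate
    exp_mean = mean_gap_target - ibi_s - mean_burst_dur
    if exp_mean <= 0:
        raise ParameterError(
            "mean_rate too high for the configured burst structure"
        )

    spikes: list[float] = []
    t = rng.exponential(exp_mean)
    while t < duration:
        n_sp = 2 + rng.poisson(m - 2.0)
        isis = spec.intra_burst_isi * rng.uniform(0.7, 1.1, n_sp - 1) / 1e3
        burst_times = t + np.concatenate(([0.0], np.cumsum(isis)))
        spikes.extend(burst_times[burst_times < duration])
        t = burst_times[-1] + ibi_s + rng.exponential(exp_mean)
    return SpikeTrain(np.asarray(spikes))


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to [low, high] Hz.

    Corners are inset by 5% of the bandwidth so the filter skirts stay
    inside the nominal band.
    """
    white = rng.standard_normal(n)
    nyq = fs / 2
    pad = 0.05 * (high - low)
    sos = sp_signal.butter(
        4, [(low + pad) / nyq, (high - pad) / nyq], btype="band", output="sos"
    )
    shaped = sp_signal.sosfiltfilt(sos, white)
    std = shaped.std()
    return shaped / std if std > 0 else shaped


def _gap_intervals(
    bands: tuple[tuple[float, float], ...], total: tuple[float, float]
) -> list[tuple[float, float]]:
    """Sub-intervals of ``total`` not covered by any band."""
    lo, hi = total
    edges = sorted((max(a, lo), min(b, hi)) for a, b in bands if b > lo and a < hi)
    gaps: list[tuple[float, float]] = []
    cursor = lo
    for a, b in edges:
        if a > cursor:
            gaps.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < hi:
        gaps.append((cursor, hi))
    return gaps


def simulate_lfp(duration: float, spec: LfpSpec, seed: int) -> LfpTrace:
    """Spectrally shaped Gaussian noise with configured relative band powers.

    The trace is a sum of band-passed white-noise components — one per
    requested band, plus components filling the gaps of the 1.5-90 Hz total
    range — on top of a flat broadband floor of ``noise_floor`` µV rms.  The
    floor's analytic in-band contribution (variance x bandwidth / Nyquist) is
    subtracted from each component's power budget, so the relative band
    powers measured on the output match the requested fractions; the total
    in-range power is scaled up when needed to keep every budget
    non-negative.  Powers are relative, so the overall amplitude is set by
    the noise floor (or is order-unity variance when the floor is zero).
    """
    if duration < 2.0:
        raise ParameterError("need at least 2 s of data for spectral content")
    nyq = spec.fs / 2
    for low, high, _ in spec.band_components:
        if high > nyq:
            raise ParameterError(f"band edge {high} Hz above Nyquist {nyq} Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * spec.fs))
    rel_sum = sum(c[2] for c in spec.band_components)
    total_lo, total_hi = TOTAL_RANGE[0], min(TOTAL_RANGE[1], nyq)
    v = spec.noise_floor**2  # white-floor variance; flat density v / nyq

    out = np.zeros(n)
    if spec.noise_floor > 0:
        out += rng.standard_normal(n) * spec.noise_floor

    # pick the total in-range power budget T: large enough that the flat
    # floor supplies at most half of any band's target and the gaps stay
    # feasible
    gaps = _gap_intervals(
        tuple((a, b) for a, b, _ in spec.band_components), (total_lo, total_hi)
    )
    gap_width = sum(b - a for a, b in gaps)
    T = 1.0
    if v > 0:
        demands = [
            2 * v * (high - low) / nyq / rel
            for low, high, rel in spec.band_components
            if rel > 0
        ]
        if rel_sum < 1 - 1e-9 and gap_width > 0:
            demands.append(v * gap_width / nyq / (1 - rel_sum))
        T = max(demands) if demands else v

    for low, high, rel in spec.band_components:
        p = rel * T - v * (high - low) / nyq
        if p <= 0:
            continue
        out += _band_limited_noise(rng, n, spec.fs, low, high) * math.sqrt(p)
    if gap_width > 0:
        gap_budget = (1 - rel_sum) * T - v * gap_width / nyq
        for a, b in gaps:
            p = gap_budget * (b - a) / gap_width
            if p > 0:
                out += _band_limited_noise(rng, n, spec.fs, a, b) * math.sqrt(p)
    return LfpTrace(samples=out, fs=spec.fs)


def _place_geometry(
    rng: np.random.Generator, config: ExperimentConfig
) -> dict[str, tuple[float, float]]:
    """Draw one unit's true COM triplet realising the configured geometry.

    D is displaced ``shift_cm`` from L1 in a random direction; L2 is L1
    rotated about D by the configured angle (random sign), so |D - L2| equals
    |D - L1| and an angle of zero gives exact light-field stability.
    """
    arena, margin = config.arena, config.field_margin
    if config.shift_cm + margin >= min(arena.width, arena.height) / 2:
        raise ParameterError("shift too large for the arena")
    for _ in range(1000):
        l1 = (
            rng.uniform(margin, arena.width - margin),
            rng.uniform(margin, arena.height - margin),
        )
        phi = rng.uniform(0, 2 * math.pi)
        d = (l1[0] + config.shift_cm * math.cos(phi), l1[1] + config.shift_cm * math.sin(phi))
        ang = math.radians(config.angle_deg) * (1 if rng.uniform() < 0.5 else -1)
        vx, vy = l1[0] - d[0], l1[1] - d[1]
        l2 = (
            d[0] + vx * math.cos(ang) - vy * math.sin(ang),
            d[1] + vx * math.sin(ang) + vy * math.cos(ang),
        )
        pts = (l1, d, l2)
        if all(
            margin <= p[0] <= arena.width - margin
            and margin <= p[1] <= arena.height - margin
            for p in pts
        ):
            return {"L1": l1, "D": d, "L2": l2}
    raise ParameterError("could not place the COM triplet inside the arena")


def _waveform_template(rng: np.random.Generator, fs: float = 48000.0) -> np.ndarray:
    """Biphasic (negative-then-positive) mean-waveform template, in µV."""
    n = 64
    t = (np.arange(n) - 20) / fs * 1e6  # µs relative to trough
    neg_amp = rng.uniform(70, 110)
    pos_amp = rng.uniform(30, 60)
    width_sd = rng.uniform(60, 90)  # µs
    wf = -neg_amp * np.exp(-(t**2) / (2 * width_sd**2)) + pos_amp * np.exp(
        -((t - 250) ** 2) / (2 * (1.6 * width_sd) ** 2)
    )
    return wf


def generate_ldl_experiment(config: ExperimentConfig, seed: int) -> LdlExperiment:
    """Simulate a full three-session light/dark/light experiment.

    Each session gets its own trajectory and LFP; place cells keep their L2
    field geometry tied to L1 through the configured angle and displacement,
    and fire at ``dark_rate_scale`` of their light rate in darkness.  Use
    :func:`placeremap.io.write_experiment` to persist the result (including
    the ground-truth manifest).
    """
    rng = np.random.default_rng(seed)
    labels = ("L1", "D", "L2")
    scales = {"L1": 1.0, "D": config.dark_rate_scale, "L2": 1.0}
    band_profiles = {
        "L1": LIGHT_BAND_PROFILE,
        "D": DARK_BAND_PROFILE,
        "L2": LIGHT_BAND_PROFILE,
    }

    place_ids = [f"pc{i:02d}" for i in range(1, config.n_place_cells + 1)]
    burst_ids = [f"bc{i:02d}" for i in range(1, config.n_burst_cells + 1)]
    true_coms = {uid: _place_geometry(rng, config) for uid in place_ids}
    unit_kinds = {uid: "place" for uid in place_ids}
    unit_kinds.update({uid: "bursting" for uid in burst_ids})
    waveforms = {
        uid: _waveform_template(rng) for uid in place_ids + burst_ids
    }

    child = np.random.SeedSequence(seed).spawn(1)[0]
    counter = np.random.default_rng(child)

    def next_seed() -> int:
        return int(counter.integers(0, 2**31 - 1))

    sessions: dict[str, SessionData] = {}
    for label in labels:
        traj = simulate_trajectory(
            config.arena, config.duration, config.mean_speed, config.sample_rate, next_seed()
        )
        spikes: dict[str, SpikeTrain] = {}
        for uid in place_ids:
            train = simulate_place_cell(
                traj,
                config.place_spec,
                true_coms[uid][label],
                scales[label],
                next_seed(),
                arena=config.arena,
            )
            spikes[uid] = replace(
                train, waveform=waveforms[uid], waveform_fs=48000.0, unit_id=uid
            )
        for uid in burst_ids:
            train = simulate_bursting_cell(config.duration, config.burst_spec, next_seed())
            spikes[uid] = replace(
                train, waveform=waveforms[uid], waveform_fs=48000.0, unit_id=uid
            )
        lfp = {
            f"ch{k}": simulate_lfp(
                config.duration,
                LfpSpec(
                    fs=config.lfp_fs,
                    band_components=band_profiles[label],
                    noise_floor=config.lfp_noise_floor,
                ),
                next_seed(),
            )
            for k in range(1, config.n_lfp_channels + 1)
        }
        sessions[label] = SessionData(
            label=label,
            arena=config.arena,
            duration=config.duration,
            trajectory=traj,
            spikes=spikes,
            lfp=lfp,
        )
    return LdlExperiment(
        config=config,
        seed=seed,
        sessions=sessions,
        true_coms=true_coms,
        unit_kinds=unit_kinds,
    )
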