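"""Rate maps, place fields, and the spatial firing statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placeremap import (
    ArenaSpec,
    InputError,
    PlaceCellSpec,
    SpikeTrain,
    Trajectory,
    UndefinedMetricError,
    compute_rate_map,
    detect_place_field,
    field_com,
    mean_speed,
    simulate_place_cell,
    simulate_trajectory,
    skaggs_information,
    spatial_coherence,
)
from placeremap.types import PlaceField

from conftest import make_rate_map, stationary_trajectory, uniform_train


class TestComputeRateMap:
    def test_stationary_dwell_gives_one_hz_in_single_bin(self, arena):
        traj = stationary_trajectory(41.0, 41.0, duration=10.0)
        spikes = uniform_train(10, 10.0)
        rm = compute_rate_map(traj, spikes, arena=arena)
        assert rm.valid_mask.sum() == 1
        iy, ix = np.argwhere(rm.valid_mask)[0]
        assert rm.rate_raw[iy, ix] == pytest.approx(1.0, rel=0.02)
        assert np.isnan(rm.rate_raw[~rm.valid_mask]).all()

    def test_spike_count_conservation_and_occupancy_total(self, arena):
        traj = simulate_trajectory(arena, 120.0, 10.0, 50.0, seed=3)
        spikes = simulate_place_cell(traj, PlaceCellSpec(), (40, 40), 1.0, seed=4)
        rm = compute_rate_map(traj, spikes, arena=arena)
        in_session = ((spikes.times >= traj.t[0]) & (spikes.times <= traj.t[-1])).sum()
        assert rm.spike_count.sum() == in_session
        assert rm.occupancy.sum() == pytest.approx(120.0, rel=0.01)

    def test_empty_spike_train_gives_zero_map(self, arena):
        traj = simulate_trajectory(arena, 60.0, 10.0, 50.0, seed=1)
        rm = compute_rate_map(traj, SpikeTrain(np.empty(0)), arena=arena)
        assert np.nansum(rm.rate_raw) == 0.0

    def test_field_localisation_near_true_com(self, arena):
        """The detected field's COM should land within two bins of the
        simulated field centre (median over seeds).  The raw argmax of the
        smoothed map is spike-noise limited at ~0.35 Hz session rates and
        only localises to within the field width."""
        com_errors, argmax_errors = [], []
        for seed in range(20):
            traj = simulate_trajectory(arena, 600.0, 10.0, 50.0, seed=seed)
            spikes = simulate_place_cell(
                traj, PlaceCellSpec(), (30.0, 55.0), 1.0, seed=100 + seed
            )
            rm = compute_rate_map(traj, spikes, arena=arena)
            f = detect_place_field(rm)
            if f is not None:
                com_errors.append(np.hypot(f.com[0] - 30.0, f.com[1] - 55.0))
            smooth = np.where(rm.valid_mask, rm.rate_smooth, -np.inf)
            iy, ix = np.unravel_index(np.argmax(smooth), smooth.shape)
            xc, yc = rm.bin_centers()
            argmax_errors.append(np.hypot(xc[ix] - 30.0, yc[iy] - 55.0))
        assert len(com_errors) >= 18
        assert np.median(com_errors) <= 2 * 2.5
        assert np.median(argmax_errors) <= 10.0  # within the field sigma


class TestDetectPlaceField:
    def test_gaussian_bump_field_contains_peak(self):
        yy, xx = np.mgrid[0:20, 0:20]
        rates = 5 * np.exp(-((xx - 10) ** 2 + (yy - 8) ** 2) / (2 * 3.0**2))
        rm = make_rate_map(rates)
        f = detect_place_field(rm)
        assert f is not None and (8, 10) in f.member_bins

    def test_uniform_map_returns_whole_area(self):
        rm = make_rate_map(np.full((6, 6), 2.0))
        f = detect_place_field(rm, min_bins=9)
        assert f is not None and len(f.member_bins) == 36

    def test_two_bumps_larger_area_wins_brute_force(self):
        """Cross-check component selection against exhaustive enumeration."""
        from scipy import ndimage

        rng = np.random.default_rng(7)
        for _ in range(20):
            rates = np.zeros((15, 15))
            # two rectangular plateaus of equal height, different area
            rates[1:4, 1:6] = 4.0  # 15 bins
            r0, c0 = rng.integers(6, 10), rng.integers(1, 8)
            h, w = rng.integers(2, 4), rng.integers(2, 4)
            rates[r0 : r0 + h, c0 : c0 + w] = 4.0
            rm = make_rate_map(rates)
            f = detect_place_field(rm, peak_fraction=0.5, min_bins=1)
            labels, n = ndimage.label(
                rates >= 2.0, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]]
            )
            best = max(
                range(1, n + 1),
                key=lambda k: ((labels == k).sum(), rates[labels == k].mean()),
            )
            expected = {tuple(map(int, rc)) for rc in np.argwhere(labels == best)}
            assert f.member_bins == expected

    def test_all_invalid_map_raises(self):
        rm = make_rate_map(np.zeros((4, 4)), valid=np.zeros((4, 4), dtype=bool))
        with pytest.raises(InputError):
            detect_place_field(rm)

    def test_too_small_component_returns_none(self):
        rates = np.zeros((10, 10))
        rates[5, 5] = 10.0
        assert detect_place_field(make_rate_map(rates), min_bins=9) is None


class TestFieldCom:
    def test_single_bin_field_is_its_centre(self):
        rates = np.zeros((32, 32))
        rates[15, 15] = 3.0  # bin centre (15.5 * 2.5) = 38.75
        rm = make_rate_map(rates)
        f = PlaceField(member_bins=frozenset({(15, 15)}), peak_rate=3.0, com=(0, 0))
        assert field_com(rm, f) == pytest.approx((38.75, 38.75))

    def test_symmetric_bump_com_at_centre(self):
        yy, xx = np.mgrid[0:32, 0:32]
        rates = np.exp(-((xx - 7.5) ** 2 + (yy - 23.5) ** 2) / 8.0)
        rm = make_rate_map(rates)
        f = detect_place_field(rm, peak_fraction=0.1, min_bins=1)
        com = field_com(rm, f)
        # bin (row 23.5 -> y 60, col 7.5 -> x 20)
        assert com[0] == pytest.approx(20.0, abs=1.25)
        assert com[1] == pytest.approx(60.0, abs=1.25)

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(11)
        rates = rng.uniform(0.1, 5.0, (10, 10))
        rm = make_rate_map(rates, bin_size=2.0)
        bins = frozenset(
            (int(r), int(c)) for r, c in rng.integers(0, 10, size=(20, 2))
        )
        f = PlaceField(member_bins=bins, peak_rate=1.0, com=(0, 0))
        sx = sy = sw = 0.0
        for r, c in bins:
            w = rates[r, c]
            sw += w
            sx += w * (c + 0.5) * 2.0
            sy += w * (r + 0.5) * 2.0
        assert field_com(rm, f) == pytest.approx((sx / sw, sy / sw), rel=1e-12)

    def test_zero_rate_field_raises(self):
        rm = make_rate_map(np.zeros((4, 4)))
        f = PlaceField(member_bins=frozenset({(1, 1)}), peak_rate=0.0, com=(0, 0))
        with pytest.raises(UndefinedMetricError):
            field_com(rm, f)


class TestSkaggsInformation:
    def test_uniform_map_is_zero(self):
        assert skaggs_information(make_rate_map(np.full((8, 8), 1.7))) == 0.0

    def test_two_bin_closed_form_is_one_bit(self):
        """Equal occupancy, rates (2, 0): I = 0.5 * 2 * log2(2) = 1 bit/spike."""
        rm = make_rate_map(np.array([[2.0, 0.0]]))
        assert skaggs_information(rm) == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(5)
        rates = rng.uniform(0, 4, (10, 10))
        occ = rng.uniform(0.1, 2.0, (10, 10))
        rm = make_rate_map(rates, occupancy=occ)
        p = occ / occ.sum()
        lam_bar = (p * rates).sum()
        oracle = sum(
            p[i, j] * (rates[i, j] / lam_bar) * np.log2(rates[i, j] / lam_bar)
            for i in range(10)
            for j in range(10)
            if rates[i, j] > 0
        )
        assert skaggs_information(rm) == pytest.approx(oracle, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0), seed=st.integers(0, 1000))
    def test_invariant_under_rate_rescaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        rates = rng.uniform(0, 3, (6, 6))
        rates.flat[0] = 1.0  # guarantee nonzero mean rate
        occ = rng.uniform(0.2, 1.0, (6, 6))
        a = skaggs_information(make_rate_map(rates, occupancy=occ))
        b = skaggs_information(make_rate_map(rates * scale, occupancy=occ))
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    def test_zero_mean_rate_raises(self):
        with pytest.raises(UndefinedMetricError):
            skaggs_information(make_rate_map(np.zeros((4, 4))))


class TestSpatialCoherence:
    def test_planar_ramp_is_near_one(self):
        yy, xx = np.mgrid[0:12, 0:12]
        rm = make_rate_map(1.0 * xx + 0.5 * yy + 1)
        assert spatial_coherence(rm) > 0.97

    def test_checkerboard_is_anticorrelated(self):
        yy, xx = np.mgrid[0:8, 0:8]
        rm = make_rate_map(((xx + yy) % 2) * 2.0 - 1.0 + 2.0)
        assert spatial_coherence(rm) < -0.5

    def test_matches_two_pass_pearson_oracle(self):
        rng = np.random.default_rng(9)
        rates = rng.uniform(0, 5, (12, 12))
        rm = make_rate_map(rates)
        nm = np.zeros_like(rates)
        for i in range(12):
            for j in range(12):
                vals = [
                    rates[a, b]
                    for a in range(i - 1, i + 2)
                    for b in range(j - 1, j + 2)
                    if (a, b) != (i, j) and 0 <= a < 12 and 0 <= b < 12
                ]
                nm[i, j] = np.mean(vals)
        x, y = rates.ravel(), nm.ravel()
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert spatial_coherence(rm) == pytest.approx(oracle, rel=1e-12)

    def test_constant_map_raises(self):
        with pytest.raises(UndefinedMetricError):
            spatial_coherence(make_rate_map(np.full((5, 5), 2.0)))


class TestMeanSpeed:
    def test_constant_velocity_line(self):
        t = np.linspace(0, 8, 81)
        traj = Trajectory(t=t, x=10 * t, y=np.zeros_like(t))
        assert mean_speed(traj) == pytest.approx(10.0)

    def test_stationary_is_zero(self):
        assert mean_speed(stationary_trajectory(40, 40, 10.0)) == 0.0

    def test_simulated_trajectory_hits_target(self, arena):
        traj = simulate_trajectory(arena, 600.0, 10.0, 50.0, seed=21)
        assert mean_speed(traj) == pytest.approx(10.0, abs=1.5)

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(InputError):
            Trajectory(t=np.array([0.0, 1.0, 1.0]), x=np.zeros(3), y=np.zeros(3))


def test_place_cell_clears_classification_thresholds_constant_cell_does_not(arena):
    """Simulated place cells must exceed the Skaggs/coherence thresholds;
    a constant-rate (non-spatial) cell at bursting rates must not look
    spatially informative."""
    hits = 0
    n_seeds = 10
    for seed in range(n_seeds):
        traj = simulate_trajectory(arena, 600.0, 10.0, 50.0, seed=seed)
        spikes = simulate_place_cell(
            traj, PlaceCellSpec(peak_rate=3.0), (45, 35), 1.0, seed=200 + seed
        )
        rm = compute_rate_map(traj, spikes, arena=arena)
        if skaggs_information(rm) >= 0.5 and spatial_coherence(rm) >= 0.25:
            hits += 1
    assert hits >= 0.9 * n_seeds

    traj = simulate_trajectory(arena, 600.0, 10.0, 50.0, seed=77)
    flat = simulate_place_cell(
        traj,
        PlaceCellSpec(peak_rate=3.0, baseline_rate=3.0),
        (40, 40),
        1.0,
        seed=78,
    )
    rm = compute_rate_map(traj, flat, arena=arena)
    assert skaggs_information(rm) < 0.5
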