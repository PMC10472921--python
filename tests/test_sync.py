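"""Phase extraction, PLV, circular-shift surrogates and delta maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gastrosync import (PhaseSeries, cross_subject_null, delta_map,
                        gastric_to_bold_grid, hilbert_phase, lagged_plv,
                        make_null_shifts, plv)
from gastrosync.sync import average_runs


def plv_bruteforce(tx, ty):
    """Scalar-loop oracle for Eq.-style PLV."""
    re = im = 0.0
    for a, b in zip(tx, ty):
        re += np.cos(a - b)
        im += np.sin(a - b)
    return np.hypot(re, im) / len(tx)


class TestHilbertPhase:
    fs = 10.0

    def test_cosine_phase_slope_matches_frequency(self):
        t = np.arange(4096) / self.fs
        ph = hilbert_phase(np.cos(2 * np.pi * 0.05 * t), self.fs)
        mid = slice(400, 3600)
        slope = np.polyfit(t[mid], np.unwrap(ph.theta)[mid], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 0.05, rel=1e-3)

    def test_sine_lags_cosine_by_half_pi(self):
        t = np.arange(4000) / self.fs  # integer cycle count: no leakage
        pc = hilbert_phase(np.cos(2 * np.pi * 0.05 * t), self.fs)
        ps = hilbert_phase(np.sin(2 * np.pi * 0.05 * t), self.fs)
        mid = slice(400, 3600)
        diff = np.angle(np.exp(1j * (ps.theta - pc.theta)))[mid]
        assert np.allclose(diff, -np.pi / 2, atol=1e-2)

    def test_quadrature_pair_phase_difference(self):
        t = np.arange(4000) / self.fs
        a = hilbert_phase(np.cos(2 * np.pi * 0.05 * t), self.fs)
        b = hilbert_phase(np.cos(2 * np.pi * 0.05 * t - np.pi / 2), self.fs)
        edge = int(0.05 * t.size)
        diff = np.angle(np.exp(1j * (a.theta - b.theta)))[edge:-edge]
        assert np.allclose(diff, np.pi / 2, atol=0.02)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            hilbert_phase(np.ones(100), self.fs)


class TestGastricToBoldGrid:
    def test_15min_recording_gives_450_then_435_samples(self):
        ph = PhaseSeries(np.linspace(-3, 3, 9000) % np.pi, fs=10.0)
        out = gastric_to_bold_grid(ph, TR=2.0, n_trim=15)
        assert len(out) == 450
        assert out.trimmed().size == 435

    def test_linear_ramp_keeps_slope(self):
        theta = 0.0005 * np.arange(9000)
        out = gastric_to_bold_grid(PhaseSeries(theta, fs=10.0), TR=2.0)
        slopes = np.diff(out.theta)
        assert np.allclose(slopes, 0.0005 * 20)

    def test_zero_trim_is_pure_decimation(self):
        theta = np.linspace(0, 1, 9000) % np.pi
        out = gastric_to_bold_grid(PhaseSeries(theta, fs=10.0), TR=2.0, n_trim=0)
        assert np.array_equal(out.theta, theta[::20])
        assert out.trimmed().size == 450


class TestPLV:
    def test_identical_phases_give_one(self, rng):
        th = rng.uniform(-np.pi, np.pi, 200)
        assert plv(th, th) == pytest.approx(1.0)

    def test_constant_lag_gives_one(self, rng):
        th = rng.uniform(-np.pi, np.pi, 200)
        assert plv(th, th + 0.7) == pytest.approx(1.0)

    def test_hand_computed_three_point_case(self):
        assert plv([0, np.pi / 2, np.pi], [0, 0, 0]) == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            tx = rng.uniform(-np.pi, np.pi, 97)
            ty = rng.uniform(-np.pi, np.pi, 97)
            assert abs(plv(tx, ty) - plv_bruteforce(tx, ty)) < 1e-12

    def test_independent_phases_match_random_walk_expectation(self, rng):
        T = 10_000
        vals = [plv(rng.uniform(-np.pi, np.pi, T), rng.uniform(-np.pi, np.pi, T))
                for _ in range(300)]
        expected = 0.5 * np.sqrt(np.pi / T)
        assert abs(np.mean(vals) - expected) < 0.5 * expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            plv(np.zeros(10), np.zeros(11))

    @given(st.floats(-10, 10), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_global_phase_offset(self, offset, seed):
        r = np.random.default_rng(seed)
        tx = r.uniform(-np.pi, np.pi, 64)
        ty = r.uniform(-np.pi, np.pi, 64)
        assert plv(tx + offset, ty) == pytest.approx(plv(tx, ty), abs=1e-10)
        assert plv(tx, ty + offset) == pytest.approx(plv(tx, ty), abs=1e-10)


class TestNullShifts:
    @pytest.mark.parametrize("n,expected", [(450, 360), (300, 210)])
    def test_surrogate_counts_for_run_lengths(self, n, expected):
        spec = make_null_shifts(n)
        assert spec.n_null == expected
        assert 0 not in spec.lags

    def test_lags_respect_guard_on_both_sides(self):
        spec = make_null_shifts(450)
        assert spec.lags.min() == 45
        assert spec.lags.max() == 404

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            make_null_shifts(90)  # exactly 2 L


class TestLaggedPLV:
    def test_matches_roll_and_recompute_oracle(self, rng):
        N, V, trim = 150, 9, 12
        bt = rng.uniform(-np.pi, np.pi, (V, N))
        gt = rng.uniform(-np.pi, np.pi, N)
        lags = np.array([1, 17, 60, 149])
        fast = lagged_plv(bt, gt, lags, n_trim=trim)
        for j, k in enumerate(lags):
            g = np.roll(gt, k)
            for v in range(V):
                slow = plv_bruteforce(g[trim:], bt[v, trim:])
                assert fast[v, j] == pytest.approx(slow, abs=1e-12)

    def test_zero_lag_equals_empirical_plv(self, rng):
        bt = rng.uniform(-np.pi, np.pi, (3, 100))
        gt = rng.uniform(-np.pi, np.pi, 100)
        fast = lagged_plv(bt, gt, np.array([0]), n_trim=10)
        ref = plv(gt[10:], bt[:, 10:])
        assert np.allclose(fast[:, 0], ref, atol=1e-12)


class TestDeltaMap:
    def make_inputs(self, rng, couple_first=True):
        N = 300
        gastric = np.cumsum(rng.normal(0.6, 0.25, N)) % (2 * np.pi) - np.pi
        gp = PhaseSeries(gastric, fs=0.5, n_trimmed=15)
        voxels = rng.uniform(-np.pi, np.pi, (20, N))
        if couple_first:
            voxels[0] = gastric
        nulls = make_null_shifts(N)
        return voxels, gp, nulls

    def test_copied_gastric_phase_yields_plv_one_positive_delta(self, rng):
        voxels, gp, nulls = self.make_inputs(rng)
        emp, med, dlt = delta_map(voxels, gp, nulls)
        assert emp.values[0] == pytest.approx(1.0, abs=1e-9)
        assert dlt.values[0] > 0

    def test_independent_voxels_have_small_delta(self, rng):
        deltas = []
        for _ in range(25):
            voxels, gp, nulls = self.make_inputs(rng, couple_first=False)
            _, _, dlt = delta_map(voxels, gp, nulls)
            deltas.append(dlt.values)
        assert abs(np.mean(deltas)) < 0.05

    def test_null_median_calibration_for_independent_voxels(self, rng):
        below = []
        for _ in range(25):
            voxels, gp, nulls = self.make_inputs(rng, couple_first=False)
            emp, med, _ = delta_map(voxels, gp, nulls)
            below.append(emp.values < med.values)
        frac = np.mean(below)
        assert 0.4 <= frac <= 0.6

    def test_average_of_identical_runs_equals_each(self, rng):
        voxels, gp, nulls = self.make_inputs(rng)
        _, _, d1 = delta_map(voxels, gp, nulls)
        _, _, d2 = delta_map(voxels, gp, nulls)
        avg = average_runs([d1, d2])
        assert np.array_equal(avg.values, d1.values)
        assert avg.runs_averaged == 2

    def test_delta_values_bounded(self, rng):
        voxels, gp, nulls = self.make_inputs(rng)
        _, _, dlt = delta_map(voxels, gp, nulls)
        assert np.all(np.abs(dlt.values) <= 1)


class TestCrossSubjectNull:
    def test_own_stomach_excluded_and_centered_nulls(self, rng):
        N = 240
        phases = {}
        gastric = {}
        for s in ("a", "b", "c"):
            g = np.cumsum(rng.normal(0.6, 0.3, N)) % (2 * np.pi) - np.pi
            gastric[s] = PhaseSeries(g, fs=0.5, n_trimmed=15)
            v = rng.uniform(-np.pi, np.pi, (10, N))
            v[0] = g  # each brain locked to its OWN stomach only
            phases[s] = v
        out = cross_subject_null(phases, gastric)
        # the locked voxel should NOT show high PLV against other stomachs
        assert out["a"][0] < 0.5
        assert np.mean([m.mean() for m in out.values()]) < 0.3

    def test_single_subject_rejected(self, rng):
        g = PhaseSeries(rng.uniform(-np.pi, np.pi, 100), fs=0.5)
        with pytest.raises(ValueError, match="two subjects"):
            cross_subject_null({"a": np.zeros((2, 100))}, {"a": g})

    def test_unequal_lengths_truncated(self, rng):
        g1 = PhaseSeries(rng.uniform(-np.pi, np.pi, 120), fs=0.5)
        g2 = PhaseSeries(rng.uniform(-np.pi, np.pi, 100), fs=0.5)
        out = cross_subject_null(
            {"a": rng.uniform(-np.pi, np.pi, (3, 120)),
             "b": rng.uniform(-np.pi, np.pi, (3, 100))},
            {"a": g1, "b": g2}, n_trim=10)
        assert out["a"].shape == (3,)
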