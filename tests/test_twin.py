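import numpy as np
import pytest

from metastab.containers import Connectome
from metastab.synth import SyntheticConnectomeSpec, generate_connectome
from metastab.twin import (TwinParams, apply_tms_reset, assign_frequencies,
                           find_low_coherence_times, seed_average,
                           segmented_metastability, select_subgroup, simulate,
                           tune_working_point)


def _all_to_all(n, coords_scale=10.0):
    w = np.ones((n, n)) - np.eye(n)
    d = np.zeros((n, n))
    coords = np.arange(n)[:, None] * np.array([[coords_scale, 0.0, 0.0]])
    return Connectome(weights=w, distances=d, delays=d, coordinates=coords)


class TestAssignFrequencies:
    def test_endpoints(self):
        omega = assign_frequencies(np.array([0.0, 1.0]), f_max=15.0, f_spread=3.0)
        f = omega * 1000 / (2 * np.pi)
        np.testing.assert_allclose(f, [15.0, 12.0])

    def test_fmax_shift_is_translation(self):
        s = np.array([0.1, 0.5, 0.9, 1.7])
        f1 = assign_frequencies(s, 15.0, 3.0) * 1000 / (2 * np.pi)
        f2 = assign_frequencies(s, 25.0, 3.0) * 1000 / (2 * np.pi)
        np.testing.assert_allclose(f2 - f1, 10.0)

    def test_max_is_fmax(self):
        s = np.random.default_rng(0).uniform(1, 5, 30)
        f = assign_frequencies(s, 35.0, 3.0) * 1000 / (2 * np.pi)
        assert f.max() == pytest.approx(35.0)
        assert f.min() == pytest.approx(32.0)

    def test_equal_strengths_error(self):
        with pytest.raises(ValueError, match="equal"):
            assign_frequencies(np.ones(5), 15.0)


class TestSimulate:
    def test_decoupled_closed_form(self):
        conn = _all_to_all(5)
        omega = np.linspace(0.05, 0.09, 5)
        p = TwinParams(omega=omega, coupling=0.0, noise_scale=0.0, dt=0.25,
                       duration_ms=200.0, seed=4)
        run = simulate(conn, p)
        t = run.times_ms
        theta0 = run.theta[:, 0]
        exact = theta0[:, None] + omega[:, None] * t[None, :]
        err = np.abs(np.angle(np.exp(1j * (run.theta - exact))))
        assert err.max() < 1e-10

    def test_two_oscillator_sync(self):
        conn = _all_to_all(2)
        p = TwinParams(omega=np.array([0.06, 0.06]), coupling=2.0,
                       noise_scale=0.0, dt=0.1, duration_ms=500.0, seed=1)
        run = simulate(conn, p)
        diff = np.angle(np.exp(1j * (run.theta[0, -1] - run.theta[1, -1])))
        assert abs(diff) < 1e-6
        assert run.kop_trace().r[0, -1] > 0.999999

    def test_strong_coupling_sync_attractor(self):
        conn = _all_to_all(12)
        p = TwinParams(omega=np.full(12, 2 * np.pi * 10 / 1000), coupling=5.0,
                       noise_scale=0.0, dt=0.1, duration_ms=600.0, seed=2)
        run = simulate(conn, p)
        assert run.kop_trace().r[0, -1] > 0.99

    def test_seed_determinism(self):
        conn = generate_connectome(SyntheticConnectomeSpec(n_nodes=20, seed=5))
        omega = assign_frequencies(conn.strengths, 15.0, 3.0)
        p = TwinParams(omega=omega, coupling=0.1, noise_scale=1.0, dt=0.5,
                       duration_ms=300.0, seed=77)
        a = simulate(conn, p)
        b = simulate(conn, p)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_dt_larger_than_min_delay_error(self):
        conn = generate_connectome(SyntheticConnectomeSpec(n_nodes=20, seed=5))
        omega = assign_frequencies(conn.strengths, 15.0, 3.0)
        p = TwinParams(omega=omega, coupling=0.1, dt=5.0, duration_ms=100.0)
        with pytest.raises(ValueError, match="delay"):
            simulate(conn, p)

    def test_dt_halving_stability(self):
        conn = generate_connectome(SyntheticConnectomeSpec(n_nodes=20, seed=5))
        omega = assign_frequencies(conn.strengths, 15.0, 3.0)
        runs = {}
        for dt in (0.5, 0.25):
            p = TwinParams(omega=omega, coupling=0.05, noise_scale=0.0, dt=dt,
                           duration_ms=2000.0, seed=3)
            runs[dt] = simulate(conn, p)
        r_coarse = runs[0.5].kop_trace().r[0].mean()
        r_fine = runs[0.25].kop_trace().r[0].mean()
        assert abs(r_coarse - r_fine) / r_fine < 0.02


class TestLowCoherenceTimes:
    def test_sinusoid_troughs(self):
        dt = 0.5
        t = np.arange(0, 8000, dt)
        r = 0.5 + 0.3 * np.sin(2 * np.pi * t / 1000.0)
        times = find_low_coherence_times(r, dt, burn_in_ms=2000.0)
        # troughs of sin at 750 + 1000k ms
        expected = np.arange(2750, 8000, 1000.0)
        assert times.size >= expected.size - 1
        for got in times:
            assert np.min(np.abs(expected - got)) < 30.0

    def test_constant_trace_error(self):
        with pytest.raises(ValueError, match="troughs"):
            find_low_coherence_times(np.full(10000, 0.5), 0.5, 1000.0)

    def test_smoothing_window_longer_than_trace_error(self):
        with pytest.raises(ValueError, match="longer than trace"):
            find_low_coherence_times(np.ones(10), 0.5, 1.0)


class TestReset:
    def _setup(self):
        conn = generate_connectome(SyntheticConnectomeSpec(n_nodes=30, seed=8))
        omega = assign_frequencies(conn.strengths, 15.0, 3.0)
        p = TwinParams(omega=omega, coupling=0.05, noise_scale=0.5, dt=0.5,
                       duration_ms=1500.0, seed=6)
        return conn, p

    def test_instant_set_kop_one_at_pulse(self):
        conn, p = self._setup()
        run = apply_tms_reset(conn, p, pulse_time_ms=1000.0, site_node=0,
                              instant_radius_mm=40.0)
        site_dist = np.linalg.norm(conn.coordinates - conn.coordinates[0], axis=1)
        instant = np.flatnonzero(site_dist <= 40.0)
        i_pulse = int(round(1000.0 / p.dt))
        phases = run.theta[instant, i_pulse]
        z = np.abs(np.exp(1j * phases).mean())
        assert z == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(phases, np.pi / 2, atol=1e-12)

    def test_delayed_node_resets_on_schedule(self):
        conn, p = self._setup()
        run = apply_tms_reset(conn, p, pulse_time_ms=1000.0, site_node=0,
                              instant_radius_mm=1.0)
        site_dist = np.linalg.norm(conn.coordinates - conn.coordinates[0], axis=1)
        far = int(np.argmax(site_dist))
        tau = conn.delays[far, 0]
        step = int(round((1000.0 + tau) / p.dt))
        assert run.theta[far, step] == pytest.approx(np.pi / 2, abs=1e-12)
        assert run.reset_times_ms[far] == pytest.approx(1000.0 + tau, abs=p.dt)

    def test_infinite_radius_full_network_jump(self):
        conn, p = self._setup()
        run = apply_tms_reset(conn, p, pulse_time_ms=1000.0, site_node=0,
                              instant_radius_mm=1e9)
        i_pulse = int(round(1000.0 / p.dt))
        r = run.kop_trace().r[0]
        assert r[i_pulse] == pytest.approx(1.0, abs=1e-12)

    def test_prepulse_trajectory_matches_free_run(self):
        conn, p = self._setup()
        free = simulate(conn, p)
        run = apply_tms_reset(conn, p, pulse_time_ms=1000.0, site_node=0)
        i_pulse = int(round(1000.0 / p.dt))
        np.testing.assert_array_equal(run.theta[:, : i_pulse],
                                      free.theta[:, : i_pulse])

    def test_kop_decays_after_reset_with_noise(self):
        conn, p = self._setup()
        run = apply_tms_reset(conn, p, pulse_time_ms=1000.0, site_node=0,
                              instant_radius_mm=1e9)
        r = run.kop_trace().r[0]
        i_pulse = int(round(1000.0 / p.dt))
        assert r[i_pulse + 600] < 1.0 - 1e-4


class TestSegmentedMetastability:
    def test_matches_plain_windows_away_from_pulse(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(0, 1, 2000)
        out = segmented_metastability(r, pulse_index=1000, window=100)
        # far from the pulse the clipped window is the plain centered window
        seg = r[500 - 49 : 500 + 51]
        assert out[500] == pytest.approx(seg.std(), abs=1e-12)

    def test_no_window_crosses_pulse(self):
        r = np.concatenate([np.zeros(1000), np.ones(1000)])
        out = segmented_metastability(r, pulse_index=1000, window=100)
        finite = np.isfinite(out)
        assert np.nanmax(out[finite]) == pytest.approx(0.0, abs=1e-12)

    def test_transient_zone_nan(self):
        r = np.random.default_rng(1).uniform(0, 1, 2000)
        out = segmented_metastability(r, pulse_index=1000, window=100,
                                      transient=50)
        assert np.isnan(out[1000:1050]).all()
        assert np.isfinite(out[1100])


class TestSubgroup:
    def test_zero_tolerance_includes_exact_matches(self):
        omega = 2 * np.pi * np.array([10.0, 10.0, 12.0, 14.0]) / 1000
        sel = select_subgroup(omega, target_node=0, tolerance_hz=0.0)
        assert sel.tolist() == [0, 1]

    def test_large_tolerance_all_nodes(self):
        omega = 2 * np.pi * np.array([10.0, 11.0, 12.0]) / 1000
        sel = select_subgroup(omega, 1, tolerance_hz=3.0)
        assert sel.tolist() == [0, 1, 2]

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(2)
        omega = 2 * np.pi * rng.uniform(5, 15, 40) / 1000
        sizes = [select_subgroup(omega, 7, tol).size for tol in (0.1, 0.5, 2.0, 5.0)]
        assert sizes == sorted(sizes)


class TestTuneWorkingPoint:
    def test_grid_scores_and_argmax(self):
        conn = generate_connectome(SyntheticConnectomeSpec(n_nodes=30, seed=12))
        base = TwinParams(omega=np.zeros(30), coupling=1.0, noise_scale=0.1,
                          dt=0.5, duration_ms=2500.0, seed=0)
        (k_star, v_star), table = tune_working_point(
            conn, k_grid=[0.0, 0.05, 5.0], velocity_grid=[7.0],
            base_params=base, burn_in_ms=500.0)
        assert len(table) == 3
        # K=0 is noise floor, very large K locks (r ~ const): neither optimal
        by_k = table.set_index("K")["score"]
        assert by_k[0.05] >= by_k[0.0]
        assert by_k[0.05] >= by_k[5.0]
        assert k_star == 0.05

    def test_reproducible_under_seed(self):
        conn = generate_connectome(SyntheticConnectomeSpec(n_nodes=20, seed=2))
        base = TwinParams(omega=np.zeros(20), coupling=1.0, noise_scale=0.1,
                          dt=0.5, duration_ms=1500.0, seed=5)
        _, t1 = tune_working_point(conn, [0.02, 0.2], [7.0], base)
        _, t2 = tune_working_point(conn, [0.02, 0.2], [7.0], base)
        assert t1.equals(t2)

    def test_empty_grid_error(self):
        conn = generate_connectome(SyntheticConnectomeSpec(n_nodes=10, seed=2))
        base = TwinParams(omega=np.zeros(10), coupling=1.0)
        with pytest.raises(ValueError, match="empty"):
            tune_working_point(conn, [], [7.0], base)


class TestSeedAveraging:
    def test_average_invariant_to_seed_order(self):
        conn = generate_connectome(SyntheticConnectomeSpec(n_nodes=20, seed=3))
        omega = assign_frequencies(conn.strengths, 15.0, 3.0)
        traces = []
        for seed in (0, 1, 2):
            p = TwinParams(omega=omega, coupling=0.05, noise_scale=0.5, dt=0.5,
                           duration_ms=400.0, seed=seed)
            traces.append(simulate(conn, p).kop_trace().r[0])
        fwd = seed_average(traces)
        rev = seed_average(traces[::-1])
        np.testing.assert_array_equal(fwd, rev)
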