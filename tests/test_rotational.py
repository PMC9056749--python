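"""Dipole construction, orientational correlation and relaxation times."""

import numpy as np
import pytest

from hydrolayer.rotational import (
    DivergenceError,
    compute_dipoles,
    dipole_acf,
    layer_relaxation,
    relaxation_time,
    site_resolved_tau,
    site_selection_mask,
)
from hydrolayer.correlate import CorrelationSeries
from hydrolayer.shells import LayerAssignment, LayerSpec
from hydrolayer.synthetic_data import SyntheticSpec, gen_composite, gen_rotor
from hydrolayer.trajectory_io import Box, Trajectory, water_topology


def _uniform_sphere(rng, size):
    v = rng.standard_normal((size, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestDipoles:
    def test_unit_norm_and_bisector_direction(self):
        top = water_topology(1)
        coords = np.array([[[5.0, 5, 5], [5.96, 5, 5], [5, 5.96, 5]]])
        traj = Trajectory(times=[0.0], coords=coords, box=Box.cubic(10.0), topology=top)
        mu = compute_dipoles(traj)
        np.testing.assert_allclose(np.linalg.norm(mu, axis=-1), 1.0, atol=1e-10)
        expect = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        np.testing.assert_allclose(mu[0, 0], expect, atol=1e-10)

    def test_split_molecule_across_boundary_handled(self):
        top = water_topology(1)
        coords = np.array([[[9.9, 5, 5], [0.86, 5, 5], [9.9, 5.96, 5]]])
        traj = Trajectory(times=[0.0], coords=coords, box=Box.cubic(10.0), topology=top)
        mu = compute_dipoles(traj)[0, 0]
        expect = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        np.testing.assert_allclose(mu, expect, atol=1e-10)


class TestDipoleACF:
    def test_frozen_dipoles_stay_at_one(self):
        rng = np.random.default_rng(0)
        u = np.broadcast_to(_uniform_sphere(rng, 10), (50, 10, 3)).copy()
        series = dipole_acf(u, np.arange(50) * 0.1)
        np.testing.assert_allclose(series.values, 1.0, atol=1e-12)

    def test_rerandomized_dipoles_decorrelate_immediately(self):
        rng = np.random.default_rng(1)
        u = _uniform_sphere(rng, 200 * 40).reshape(40, 200, 3)
        series = dipole_acf(u, np.arange(40) * 0.1)
        assert series.values[0] == pytest.approx(1.0)
        assert np.max(np.abs(series.values[1:])) < 0.05

    def test_fft_path_equals_strided_loop(self):
        res = gen_rotor(SyntheticSpec(kind="rotor", n_particles=20, n_frames=100,
                                      dt=0.1, box_length=10, seed=2, params={"D_r": 0.05}))
        t = res.spec.times
        member = np.random.default_rng(3).random((100, 20)) < 0.6
        a = dipole_acf(res.dipoles, t, member=member)
        b = dipole_acf(res.dipoles, t, member=member, origin_stride=1, max_lag=99)
        # force the non-FFT path via a stride of 1 but explicit loop comparison
        num = np.zeros(100)
        cnt = np.zeros(100)
        for lag in range(100):
            for t0 in range(100 - lag):
                dots = np.einsum("nk,nk->n", res.dipoles[t0], res.dipoles[t0 + lag])
                num[lag] += dots[member[t0]].sum()
                cnt[lag] += member[t0].sum()
        oracle = num / cnt
        np.testing.assert_allclose(a.values, oracle / oracle[0], rtol=1e-9)
        np.testing.assert_allclose(b.values, a.values, rtol=1e-12)
        np.testing.assert_array_equal(a.counts, cnt.astype(int))

    def test_rotor_matches_exponential_closed_form(self):
        spec = SyntheticSpec(kind="rotor", n_particles=300, n_frames=2000,
                             dt=0.1, box_length=10, seed=4, params={"D_r": 0.025})
        res = gen_rotor(spec)
        series = dipole_acf(res.dipoles, spec.times, max_lag=1000)
        expect = np.exp(-2 * 0.025 * series.lags)
        assert np.max(np.abs(series.values - expect)) < 0.05

    def test_origin_stride_consistency(self):
        spec = SyntheticSpec(kind="rotor", n_particles=100, n_frames=500,
                             dt=0.1, box_length=10, seed=5, params={"D_r": 0.05})
        res = gen_rotor(spec)
        a = dipole_acf(res.dipoles, spec.times, max_lag=200)
        b = dipole_acf(res.dipoles, spec.times, max_lag=200, origin_stride=2)
        assert np.max(np.abs(a.values - b.values)) < 0.03


class TestRelaxationTime:
    def test_exact_exponential_integral(self):
        t = np.arange(0, 60, 0.05)
        series = CorrelationSeries(t, np.exp(-t / 5.0), np.ones_like(t))
        rt = relaxation_time(series)
        assert rt.tau_R == pytest.approx(5.0, rel=0.01)
        assert rt.tau_single_exp == pytest.approx(5.0, rel=0.01)

    def test_constant_correlation_diverges(self):
        t = np.arange(0, 10, 0.1)
        with pytest.raises(DivergenceError):
            relaxation_time(CorrelationSeries(t, np.ones_like(t), np.ones_like(t)))

    def test_tail_extrapolation_compensates_truncation(self):
        """Integrating only to 2τ still recovers τ via the fitted tail."""
        t = np.arange(0, 10.0, 0.05)  # 2τ for τ = 5
        series = CorrelationSeries(t, np.exp(-t / 5.0), np.ones_like(t))
        rt = relaxation_time(series)
        assert rt.tau_tail > 0
        assert rt.tau_R == pytest.approx(5.0, rel=0.02)

    def test_rotor_relaxation_time_recovery(self):
        spec = SyntheticSpec(kind="rotor", n_particles=300, n_frames=3000,
                             dt=0.1, box_length=10, seed=6, params={"D_r": 0.025})
        res = gen_rotor(spec)
        series = dipole_acf(res.dipoles, spec.times, max_lag=1500)
        assert relaxation_time(series).tau_R == pytest.approx(20.0, rel=0.10)

    def test_invariance_under_global_rotation(self):
        from scipy.spatial.transform import Rotation

        spec = SyntheticSpec(kind="rotor", n_particles=50, n_frames=400,
                             dt=0.1, box_length=10, seed=7, params={"D_r": 0.05})
        u = gen_rotor(spec).dipoles
        R = Rotation.from_euler("zyx", [0.4, -0.9, 1.3]).as_matrix()
        a = dipole_acf(u, spec.times)
        b = dipole_acf(u @ R.T, spec.times)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)


class TestSiteResolved:
    def test_all_water_selection_equals_global_acf(self):
        spec = SyntheticSpec(kind="composite", n_particles=20, n_frames=250,
                             dt=0.1, box_length=25.0, seed=8,
                             params={"D": 0.1, "D_r": 0.1})
        res = gen_composite(spec)
        traj = res.trajectory
        mu = compute_dipoles(traj)
        res_site = site_resolved_tau(traj, "SITE", cutoff=100.0, dipoles=mu, max_lag=200)
        global_series = dipole_acf(mu, traj.times, max_lag=200)
        np.testing.assert_allclose(res_site.series.values, global_series.values, rtol=1e-9)

    def test_partition_average_equals_global(self):
        """Population-weighted mean of disjoint-group C(t) equals global C(t)."""
        spec = SyntheticSpec(kind="rotor", n_particles=60, n_frames=200,
                             dt=0.1, box_length=10, seed=9, params={"D_r": 0.05})
        u = gen_rotor(spec).dipoles
        t = spec.times
        m1 = np.zeros((200, 60), dtype=bool)
        m1[:, :25] = True
        m2 = ~m1
        s1 = dipole_acf(u, t, member=m1)
        s2 = dipole_acf(u, t, member=m2)
        sg = dipole_acf(u, t)
        w1, w2 = 25 / 60, 35 / 60
        np.testing.assert_allclose(w1 * s1.values + w2 * s2.values, sg.values, atol=1e-9)

    def test_two_population_slow_site_recovery(self):
        """Site selection isolates the slow rotors around the dummy site."""
        slow = gen_rotor(SyntheticSpec(kind="rotor", n_particles=300, n_frames=3000,
                                       dt=0.1, box_length=10, seed=10,
                                       params={"D_r": 0.025}))
        fast = gen_rotor(SyntheticSpec(kind="rotor", n_particles=300, n_frames=3000,
                                       dt=0.1, box_length=10, seed=11,
                                       params={"D_r": 0.25}))
        u = np.concatenate([slow.dipoles, fast.dipoles], axis=1)
        member = np.zeros((3000, 600), dtype=bool)
        member[:, :300] = True  # "near the site" = the slow population
        series = dipole_acf(u, slow.spec.times, member=member, max_lag=1500)
        assert relaxation_time(series).tau_R == pytest.approx(20.0, rel=0.10)

    def test_unknown_group_raises(self, tracer_trajectory):
        wrapped, _ = tracer_trajectory
        with pytest.raises(KeyError):
            site_selection_mask(wrapped, "NH3", 4.0)
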