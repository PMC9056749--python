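"""MSD, generalized Einstein fits, regime classification and van Hove."""

import numpy as np
import pytest

from hydrolayer.shells import LayerAssignment, LayerSpec
from hydrolayer.synthetic_data import SyntheticSpec, gen_ballistic, gen_brownian, gen_levy_hop
from hydrolayer.trajectory_io import unwrap
from hydrolayer.translational import (
    classify_regime,
    find_secondary_modes,
    fit_power_law,
    msd_from_positions,
    msd_layered,
    van_hove_self,
)


def brute_force_msd(pos, member=None, membership="continuous"):
    """O(F²·N) double loop over origins and lags — the reference estimator."""
    F, N = pos.shape[:2]
    msd = np.zeros(F)
    counts = np.zeros(F, dtype=int)
    for lag in range(F):
        acc = 0.0
        c = 0
        for t0 in range(F - lag):
            for n in range(N):
                if member is not None:
                    if membership == "continuous":
                        if not member[t0 : t0 + lag + 1, n].all():
                            continue
                    elif not (member[t0, n] and member[t0 + lag, n]):
                        continue
                acc += np.sum((pos[t0 + lag, n] - pos[t0, n]) ** 2)
                c += 1
        msd[lag] = acc / c if c else np.nan
        counts[lag] = c
    return msd, counts


def _assignment(labels):
    labels = np.asarray(labels)
    return LayerAssignment(spec=LayerSpec((0.0, 4.0)), distances=np.zeros(labels.shape),
                           labels=labels, water_mol_ids=np.arange(labels.shape[1]))


class TestMSD:
    def test_stationary_is_zero(self):
        pos = np.ones((20, 3, 3))
        res = msd_from_positions(pos, np.arange(20) * 0.1)
        np.testing.assert_allclose(res.msd, 0.0, atol=1e-12)

    def test_ballistic_closed_form(self):
        t = np.arange(50) * 0.1
        v = np.array([[1.0, 0, 0], [0, 2.0, 0]])
        pos = v[None] * t[:, None, None]
        res = msd_from_positions(pos, t)
        expect = np.mean(np.sum(v**2, axis=1)) * t**2
        np.testing.assert_allclose(res.msd, expect, rtol=1e-9)

    def test_fft_path_equals_double_loop(self):
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.normal(0, 0.3, (60, 4, 3)), axis=0)
        res = msd_from_positions(pos, np.arange(60) * 0.1)
        oracle, counts = brute_force_msd(pos)
        np.testing.assert_allclose(res.msd, oracle, rtol=1e-9, atol=1e-12)
        np.testing.assert_array_equal(res.counts, counts)

    def test_layered_path_equals_double_loop(self):
        rng = np.random.default_rng(1)
        pos = np.cumsum(rng.normal(0, 0.3, (40, 5, 3)), axis=0)
        member = rng.random((40, 5)) < 0.7
        for rule in ("continuous", "endpoints"):
            res = msd_from_positions(pos, np.arange(40) * 0.1, member=member,
                                     membership=rule)
            oracle, counts = brute_force_msd(pos, member, rule)
            np.testing.assert_allclose(res.msd, oracle, rtol=1e-9, atol=1e-12)
            np.testing.assert_array_equal(res.counts, counts)

    def test_union_restriction_equals_unrestricted(self):
        rng = np.random.default_rng(2)
        pos = np.cumsum(rng.normal(0, 0.3, (30, 4, 3)), axis=0)
        t = np.arange(30) * 0.1
        always = np.ones((30, 4), dtype=bool)
        a = msd_from_positions(pos, t, member=always)
        b = msd_from_positions(pos, t)
        np.testing.assert_allclose(a.msd, b.msd, rtol=1e-12)

    def test_empty_lag_flagged_missing_not_zero(self):
        pos = np.cumsum(np.ones((10, 1, 3)), axis=0)
        member = np.zeros((10, 1), dtype=bool)
        member[:3] = True  # continuous residence only over the first 3 frames
        res = msd_from_positions(pos, np.arange(10) * 1.0, member=member)
        assert np.isnan(res.msd[5])
        assert res.counts[5] == 0

    def test_wrapped_trajectory_rejected(self, tracer_trajectory):
        wrapped, _ = tracer_trajectory
        with pytest.raises(ValueError, match="unwrap"):
            msd_layered(wrapped)

    def test_subset_self_consistency(self):
        """α estimates from disjoint particle halves agree within noise."""
        spec = SyntheticSpec(kind="brownian", n_particles=100, n_frames=800,
                             dt=0.1, box_length=50.0, seed=5, params={"D": 0.2})
        pos = gen_brownian(spec).ground_truth["unwrapped"]
        t = spec.times
        alphas = []
        for half in (pos[:, :50], pos[:, 50:]):
            fit = fit_power_law(msd_from_positions(half, t), (0.1, 10.0))
            alphas.append(fit.alpha)
        assert abs(alphas[0] - alphas[1]) < 0.05


class TestPowerLawFit:
    def test_linear_msd_gives_unit_alpha_and_d(self):
        t = np.arange(100) * 0.1
        res = msd_from_positions(np.zeros((100, 1, 3)), t)
        res.msd = 6.0 * t
        fit = fit_power_law(res)
        assert fit.alpha == pytest.approx(1.0, abs=1e-12)
        assert fit.D == pytest.approx(6.0, rel=1e-12)
        assert fit.D_self == pytest.approx(1.0, rel=1e-12)

    def test_quadratic_msd_gives_alpha_two(self):
        t = np.arange(100) * 0.1
        res = msd_from_positions(np.zeros((100, 1, 3)), t)
        res.msd = t**2
        assert fit_power_law(res).alpha == pytest.approx(2.0, abs=1e-12)

    def test_brownian_recovery(self):
        spec = SyntheticSpec(kind="brownian", n_particles=200, n_frames=2000,
                             dt=0.1, box_length=50.0, seed=8, params={"D": 0.2})
        res = gen_brownian(spec)
        msd = msd_layered(unwrap(res.trajectory))
        fit = fit_power_law(msd, (0.1, 20.0))
        assert 0.95 <= fit.alpha <= 1.05
        assert fit.D_self == pytest.approx(0.2, rel=0.05)

    def test_too_few_points_rejected(self):
        t = np.arange(4) * 0.1
        res = msd_from_positions(np.zeros((4, 1, 3)), t)
        res.msd = 6.0 * t
        with pytest.raises(ValueError, match="need >= 5"):
            fit_power_law(res)


class TestRegime:
    @pytest.mark.parametrize("alpha,label", [
        (0.87, "sub-diffusive"),
        (1.0, "diffusive"),
        (1.04, "diffusive"),
        (1.53, "super-diffusive"),
        (2.0, "ballistic"),
    ])
    def test_labels(self, alpha, label):
        assert classify_regime(alpha).label == label

    def test_near_two_is_super_diffusive_with_note(self):
        r = classify_regime(1.99)
        assert r.label == "super-diffusive"
        assert r.note == "near-ballistic"


class TestVanHove:
    def test_stationary_probability_in_first_bin(self):
        pos = np.ones((20, 5, 3))
        vh = van_hove_self(pos, [1.0], bins=10, times=np.arange(20) * 1.0)
        width = np.diff(vh.bin_edges)[0]
        assert vh.densities[0, 0] == pytest.approx(1.0 / width)
        assert np.all(vh.densities[0, 1:] == 0)

    def test_normalization_at_every_lag(self):
        spec = SyntheticSpec(kind="brownian", n_particles=50, n_frames=300,
                             dt=0.1, box_length=50.0, seed=3, params={"D": 0.2})
        pos = gen_brownian(spec).ground_truth["unwrapped"]
        vh = van_hove_self(pos, [1.0, 5.0, 10.0], bins=60, times=spec.times)
        widths = np.diff(vh.bin_edges)
        for row in vh.densities:
            assert np.sum(row * widths) == pytest.approx(1.0, abs=1e-9)

    def test_brownian_matches_gaussian_closed_form(self):
        D, lag = 0.2, 5.0
        spec = SyntheticSpec(kind="brownian", n_particles=400, n_frames=400,
                             dt=0.1, box_length=50.0, seed=4, params={"D": D})
        pos = gen_brownian(spec).ground_truth["unwrapped"]
        vh = van_hove_self(pos, [lag], bins=50, times=spec.times)
        r = vh.bin_centers
        gauss = 4 * np.pi * r**2 * (4 * np.pi * D * lag) ** -1.5 * np.exp(-r**2 / (4 * D * lag))
        assert np.max(np.abs(vh.densities[0] - gauss)) < 0.05 * gauss.max()

    def test_hop_fixture_shows_secondary_mode_brownian_does_not(self):
        hop_spec = SyntheticSpec(kind="levy_hop", n_particles=200, n_frames=250,
                                 dt=0.1, box_length=40.0, seed=6,
                                 params={"hop_length": 8.0, "tau_wait": 10.0})
        pos = gen_levy_hop(hop_spec).ground_truth["unwrapped"]
        vh = van_hove_self(pos, [10.0], bins=np.linspace(0, 36, 145), times=hop_spec.times)
        modes = find_secondary_modes(vh, 10.0)
        assert any(7.0 <= m <= 9.0 for m in modes)
        ctrl_spec = SyntheticSpec(kind="brownian", n_particles=200, n_frames=250,
                                  dt=0.1, box_length=40.0, seed=6, params={"D": 0.2})
        ctrl = gen_brownian(ctrl_spec).ground_truth["unwrapped"]
        vh_ctrl = van_hove_self(ctrl, [10.0], bins=np.linspace(0, 36, 145), times=ctrl_spec.times)
        assert not any(7.0 <= m <= 9.0 for m in find_secondary_modes(vh_ctrl, 10.0))

    def test_truncating_bins_rejected(self):
        spec = SyntheticSpec(kind="brownian", n_particles=20, n_frames=100,
                             dt=0.1, box_length=50.0, seed=1, params={"D": 0.5})
        pos = gen_brownian(spec).ground_truth["unwrapped"]
        with pytest.raises(ValueError, match="cover"):
            van_hove_self(pos, [5.0], bins=np.linspace(0, 0.5, 6), times=spec.times)
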