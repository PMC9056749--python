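"""Hydrogen-bond detection against brute force, statistics, lifetimes, maps."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from hydrolayer.correlate import CorrelationSeries, fit_double_exponential
from hydrolayer.hbond import (
    HBondCriteria,
    detect_hbonds,
    detect_hbonds_trajectory,
    hb_population_correlation,
    hydration_density_map,
    nhb_per_layer,
    nhb_per_water,
)
from hydrolayer.shells import LayerSpec, assign_layers
from hydrolayer.synthetic_data import gen_hb_lattice
from hydrolayer.trajectory_io import Box, Topology, Trajectory, water_topology

from conftest import random_water_frame


def brute_force_hbonds(coords, top, box, criteria=HBondCriteria()):
    """Independent oracle: all donor-H × acceptor pairs, distances by explicit
    minimisation over the 27 neighbour images."""
    L = box.lengths
    shifts = np.array([[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]) * L

    def dist(a, b):
        return min(np.linalg.norm(coords[a] - (coords[b] + s)) for s in shifts)

    o_idx = top.water_oxygen_indices
    h_idx = top.water_hydrogen_indices
    found = set()
    for dw in range(len(o_idx)):
        for col in range(2):
            h = h_idx[dw, col]
            for aw in range(len(o_idx)):
                if aw == dw:
                    continue
                a = o_idx[aw]
                if dist(h, a) < criteria.ho_max and dist(o_idx[dw], a) < criteria.oo_max:
                    found.add((int(h), int(a)))
    return found


class TestCriteria:
    def test_bonded_dimer(self, water_dimer):
        coords, top, box = water_dimer
        recs = detect_hbonds(coords, top, box=box)
        assert len(recs) == 1
        assert recs.iloc[0]["d_ho"] == pytest.approx(2.4)
        assert recs.iloc[0]["d_oo"] == pytest.approx(3.3)
        assert recs.iloc[0]["pair_class"] == "ww"

    def test_ho_distance_violation(self, water_dimer):
        coords, top, box = water_dimer
        coords = coords.copy()
        coords[1] = [0.7, 0.0, 0.0]  # H···O becomes 2.6 Å
        assert len(detect_hbonds(coords, top, box=box)) == 0

    def test_oo_distance_violation(self, water_dimer):
        coords, top, box = water_dimer
        coords = coords.copy()
        coords[3:] += [0.3, 0, 0]  # O···O becomes 3.6 Å
        assert len(detect_hbonds(coords, top, box=box)) == 0

    def test_angle_criterion_only_removes_bonds(self):
        for seed in range(5):
            coords, top, box = random_water_frame(40, 12.0, seed)
            loose = detect_hbonds(coords, top, HBondCriteria(), box=box)
            tight = detect_hbonds(coords, top, HBondCriteria(angle_max=30.0), box=box)
            assert len(tight) <= len(loose)
            key = lambda df: {(h, a) for h, a in zip(df["donor_h"], df["acceptor_atom"])}
            assert key(tight) <= key(loose)

    def test_lattice_interior_coordination(self):
        """Tetrahedral lattice: every molecule donates 2 and accepts 2."""
        res = gen_hb_lattice(2.8, 2)
        recs = detect_hbonds(res.trajectory.coords[0], res.topology,
                             box=res.trajectory.box)
        donated = recs.groupby("donor_mol").size()
        accepted = recs.groupby("acceptor_mol").size()
        assert (donated == 2).all() and len(donated) == res.topology.n_waters
        assert (accepted == 2).all() and len(accepted) == res.topology.n_waters

    def test_brute_force_equivalence(self):
        for seed in range(10):
            coords, top, box = random_water_frame(50, 12.0, seed)
            recs = detect_hbonds(coords, top, box=box)
            got = {(int(h), int(a)) for h, a in zip(recs["donor_h"], recs["acceptor_atom"])}
            assert got == brute_force_hbonds(coords, top, box)

    def test_invariance_under_rigid_motion_and_relabel(self):
        coords, top, box = random_water_frame(30, 12.0, 3)
        base = detect_hbonds(coords, top)  # no box: free cluster
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 0.8]).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -2.0, 1.0])
        assert len(detect_hbonds(moved, top)) == len(base)
        # reverse the molecule order
        n = top.n_waters
        perm = np.concatenate([[3 * (n - 1 - w), 3 * (n - 1 - w) + 1, 3 * (n - 1 - w) + 2]
                               for w in range(n)])
        assert len(detect_hbonds(coords[perm], top)) == len(base)


class TestPerLayerStats:
    def _lattice_traj(self, n_frames=3):
        res = gen_hb_lattice(2.8, 2)
        base = res.trajectory
        coords = np.repeat(base.coords, n_frames, axis=0)
        # prepend a far-away solute atom so layers can be assigned
        sol = np.tile(np.array([[0.1, 0.1, 0.1]]), (n_frames, 1, 1))
        coords = np.concatenate([sol, coords], axis=1)
        wat = res.topology
        top = Topology(
            elements=np.concatenate([np.array(["C"], dtype=object), wat.elements]),
            masses=np.concatenate([[12.0], wat.masses]),
            charges=np.concatenate([[0.0], wat.charges]),
            mol_ids=np.concatenate([[-1], wat.mol_ids]),
            roles=np.concatenate([np.array(["solute"], dtype=object), wat.roles]),
        )
        return Trajectory(times=np.arange(n_frames) * 1.0, coords=coords,
                          box=base.box, topology=top)

    def test_lattice_single_layer_mean_4_sd_0(self):
        traj = self._lattice_traj()
        a = assign_layers(traj, LayerSpec((0.0, 1000.0)))
        tbl = nhb_per_layer(traj, a)
        row = tbl[tbl["layer"] == "0-1000 A"].iloc[0]
        assert row["nhb_mean"] == pytest.approx(4.0)
        assert row["nhb_sd"] == pytest.approx(0.0)

    def test_isolated_waters_mean_zero(self):
        box = Box.cubic(30.0)
        wat = water_topology(2, first_mol_id=1)
        top = Topology(
            elements=np.concatenate([np.array(["C"], dtype=object), wat.elements]),
            masses=np.concatenate([[12.0], wat.masses]),
            charges=np.concatenate([[0.0], wat.charges]),
            mol_ids=np.concatenate([[0], wat.mol_ids]),
            roles=np.concatenate([np.array(["solute"], dtype=object), wat.roles]),
        )
        coords = np.zeros((2, 7, 3))
        coords[:, 0] = [15, 15, 15]
        coords[:, 1:4] = [[2, 2, 2], [2.96, 2, 2], [2, 2.96, 2]]
        coords[:, 4:7] = [[12, 12, 12], [12.96, 12, 12], [12, 12.96, 12]]
        traj = Trajectory(times=[0.0, 1.0], coords=coords, box=box, topology=top)
        tbl = nhb_per_layer(traj, assign_layers(traj, LayerSpec((0.0, 100.0))))
        assert tbl.iloc[0]["nhb_mean"] == pytest.approx(0.0)

    def test_counts_match_hand_rolled_oracle(self):
        coords, top, box = random_water_frame(20, 10.0, 11)
        recs = detect_hbonds(coords, top, box=box)
        counts = nhb_per_water(recs, top)[0]
        oracle = np.zeros(20)
        for h, a in brute_force_hbonds(coords, top, box):
            oracle[top.mol_ids[h]] += 1
            oracle[top.mol_ids[a]] += 1
        np.testing.assert_array_equal(counts, oracle)


def telegraph_records(n_pairs, n_frames, k_on, k_off, dt, seed):
    """Simulate independent two-state bonds; return records + state matrix."""
    rng = np.random.default_rng(seed)
    h = np.empty((n_frames, n_pairs), dtype=bool)
    h[0] = True
    p_off = 1 - np.exp(-k_off * dt)
    p_on = 1 - np.exp(-k_on * dt)
    for t in range(1, n_frames):
        r = rng.random(n_pairs)
        h[t] = np.where(h[t - 1], r >= p_off, r < p_on)
    frames, pairs = np.nonzero(h)
    recs = pd.DataFrame({
        "frame": frames,
        "donor_mol": 2 * pairs,
        "donor_h": 0, "donor_parent": 0,
        "acceptor_mol": 2 * pairs + 1,
        "acceptor_atom": 0, "d_ho": 2.0, "d_oo": 3.0,
        "pair_class": "ww",
    })
    return recs, h


class TestPopulationCorrelation:
    def test_permanent_bond_stays_at_one(self):
        recs, _ = telegraph_records(3, 50, 1.0, 0.0, 0.1, 0)
        series = hb_population_correlation(recs, n_frames=50)
        np.testing.assert_allclose(series.values, 1.0)

    def test_alternating_bond(self):
        frames = np.arange(0, 20, 2)
        recs = pd.DataFrame({"frame": frames, "donor_mol": 0, "donor_h": 0,
                             "donor_parent": 0, "acceptor_mol": 1, "acceptor_atom": 3,
                             "d_ho": 2.0, "d_oo": 3.0, "pair_class": "ww"})
        series = hb_population_correlation(recs, n_frames=20)
        np.testing.assert_allclose(series.values[:6], [1, 0, 1, 0, 1, 0])

    def test_telegraph_closed_form(self):
        """C_HB of a two-state Markov bond: p + (1-p)·exp(−(k_on+k_off)t)."""
        k_on, k_off, dt = 0.2, 0.1, 0.1
        recs, _ = telegraph_records(400, 800, k_on, k_off, dt, 42)
        series = hb_population_correlation(recs, n_frames=800, max_lag=400)
        t = series.lags * dt  # records carry unit lag spacing
        p = k_on / (k_on + k_off)
        expect = p + (1 - p) * np.exp(-(k_on + k_off) * t)
        np.testing.assert_allclose(series.values, expect, atol=0.03)

    def test_empty_statistic_raises(self):
        with pytest.raises(ValueError):
            hb_population_correlation(pd.DataFrame({"frame": [], "donor_mol": [],
                                                    "donor_h": [], "donor_parent": [],
                                                    "acceptor_mol": [], "acceptor_atom": [],
                                                    "d_ho": [], "d_oo": [],
                                                    "pair_class": []}), n_frames=10)

    def test_bounds_and_origin_value(self):
        recs, _ = telegraph_records(50, 200, 0.3, 0.3, 0.1, 7)
        series = hb_population_correlation(recs, n_frames=200)
        assert series.values[0] == 1.0
        ok = np.isfinite(series.values)
        assert (series.values[ok] >= 0).all() and (series.values[ok] <= 1.0 + 1e-12).all()


class TestDoubleExponentialFit:
    def test_single_exponential_flagged_degenerate(self):
        t = np.arange(0, 50, 0.2)
        series = CorrelationSeries(t, np.exp(-t / 7.0), np.ones_like(t))
        fit = fit_double_exponential(series)
        assert fit.degenerate
        assert fit.tau_slow == pytest.approx(7.0, rel=0.01)

    def test_noiseless_recovery_to_one_percent(self):
        t = np.arange(0, 80, 0.2)
        y = 0.4 * np.exp(-t / 2.7) + 0.6 * np.exp(-t / 13.3)
        fit = fit_double_exponential(CorrelationSeries(t, y, np.ones_like(t)))
        assert fit.tau_fast == pytest.approx(2.7, rel=0.01)
        assert fit.tau_slow == pytest.approx(13.3, rel=0.01)
        assert fit.amplitude_fast == pytest.approx(0.4, rel=0.01)


class TestDensityMap:
    def _solute_water_traj(self, water_xyz, n_frames=4, L=30.0):
        wat = water_topology(1, first_mol_id=1)
        arms = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]])
        top = Topology(
            elements=np.concatenate([np.array(["C"] * 4, dtype=object), wat.elements]),
            masses=np.concatenate([np.full(4, 12.0), wat.masses]),
            charges=np.concatenate([np.zeros(4), wat.charges]),
            mol_ids=np.concatenate([np.zeros(4, int), wat.mol_ids]),
            roles=np.concatenate([np.array(["solute"] * 4, dtype=object), wat.roles]),
        )
        coords = np.zeros((n_frames, 7, 3))
        coords[:, :4] = arms + 15.0
        coords[:, 4] = water_xyz
        coords[:, 5] = np.add(water_xyz, [0.96, 0, 0])
        coords[:, 6] = np.add(water_xyz, [0, 0.96, 0])
        box = Box.cubic(L)
        return Trajectory(times=np.arange(n_frames) * 1.0, coords=coords,
                          box=box, topology=top)

    def test_no_waters_in_cutoff_gives_zero_grid(self):
        traj = self._solute_water_traj([25.0, 25.0, 25.0])
        dmap = hydration_density_map(traj, cutoff=4.0, spacing=1.0)
        assert dmap.grid.sum() == 0.0

    def test_single_stationary_water_total_weight_one(self):
        traj = self._solute_water_traj([17.0, 15.0, 15.0])
        dmap = hydration_density_map(traj, cutoff=4.0, spacing=1.0)
        assert dmap.integral == pytest.approx(1.0)
        assert (dmap.grid > 0).sum() == 1  # all weight in one voxel

    def test_grid_integral_equals_direct_count(self):
        rng = np.random.default_rng(9)
        traj = self._solute_water_traj([17.0, 15.0, 15.0])
        # jitter the water across frames, staying near the cutoff boundary
        traj.coords[:, 4:] += rng.normal(0, 1.5, (traj.n_frames, 1, 3))
        dmap = hydration_density_map(traj, cutoff=4.0, spacing=0.5)
        o = traj.coords[:, 4]
        sol = traj.coords[0, :4]
        direct = np.mean([
            (np.linalg.norm(o[f] - sol, axis=1).min() < 4.0) for f in range(traj.n_frames)
        ])
        assert dmap.integral == pytest.approx(direct, abs=1e-9)

    def test_bad_spacing_rejected(self):
        traj = self._solute_water_traj([17.0, 15.0, 15.0])
        with pytest.raises(ValueError):
            hydration_density_map(traj, spacing=0.0)
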