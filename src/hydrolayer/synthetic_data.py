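"""Synthetic trajectories with known ground truth.

Each generator emulates one statistical structure the interfacial-water
analysis assumes — free diffusion, ballistic streaming, rest-and-jump (Lévy)
hopping, isotropic rotational diffusion, a hydrogen-bond-saturated lattice,
and two-state shell-exchange kinetics — so every downstream estimator can be
validated against closed forms or event logs without molecular-dynamics data.

Ground truth (input rates, hop logs, state series) travels alongside each
generated trajectory in :class:`SyntheticResult.ground_truth`; it is consumed
only by recovery tests, never by the analysis path itself.  Every generator
is reproducible from ``(spec, seed)`` alone, with per-particle random streams
spawned from the seed so extending ``n_frames`` leaves earlier increments
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .trajectory_io import (
    Box,
    Frame,
    Topology,
    Trajectory,
    water_topology,
    write_xyz,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticResult",
    "SyntheticSpecError",
    "gen_brownian",
    "gen_ballistic",
    "gen_levy_hop",
    "gen_rotor",
    "gen_hb_lattice",
    "gen_shell_exchange",
    "gen_composite",
    "generate",
    "write_synthetic",
]

# rigid 3-site water geometry (Å, deg): O–H 0.9572, H–O–H 104.52
OH_LENGTH = 0.9572
HOH_ANGLE_DEG = 104.52


class SyntheticSpecError(ValueError):
    """Spec parameters incompatible with the requested generator."""


@dataclass
class SyntheticSpec:
    """Full parameterisation of a generated trajectory.

    ``params`` carries kind-specific entries (D Å²/ps, speed Å/ps, hop
    length ℓ Å, mean waiting time τ_w ps, rotational diffusion constant
    D_r 1/ps, exchange rates 1/ps, O–O lattice distance Å, ...).
    """

    kind: str
    n_particles: int
    n_frames: int
    dt: float  # ps
    box_length: float  # Å (cubic)
    seed: int
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _GENERATORS and self.kind != "hb_lattice":
            raise SyntheticSpecError(f"unknown synthetic kind {self.kind!r}")
        if self.n_particles <= 0 or self.n_frames <= 0:
            raise SyntheticSpecError("n_particles and n_frames must be positive")
        if self.dt <= 0 or self.box_length <= 0:
            raise SyntheticSpecError("dt and box_length must be positive")
        for key, value in self.params.items():
            if isinstance(value, (int, float)) and key.startswith(
                ("D", "speed", "hop", "tau", "k_", "oo_", "radius")
            ):
                if value < 0:
                    raise SyntheticSpecError(f"parameter {key!r} must be >= 0")

    @property
    def box(self) -> Box:
        return Box.cubic(self.box_length)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_particles": self.n_particles,
            "n_frames": self.n_frames,
            "dt": self.dt,
            "box_length": self.box_length,
            "seed": self.seed,
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(**d)


@dataclass
class SyntheticResult:
    """A generated trajectory plus the ground truth needed for recovery tests."""

    spec: SyntheticSpec
    trajectory: Trajectory | None = None
    dipoles: np.ndarray | None = None  # (n_frames, n, 3) unit vectors (rotor kind)
    topology: Topology | None = None
    ground_truth: dict[str, Any] = field(default_factory=dict)


def _particle_rngs(spec: SyntheticSpec, n: int | None = None, *, stream: int = 0):
    """One independent Generator per particle, derived from (seed, stream)."""
    n = spec.n_particles if n is None else n
    root = np.random.SeedSequence([spec.seed, stream])
    return [np.random.default_rng(child) for child in root.spawn(n)]


def _uniform_sphere(rng: np.random.Generator, size: int = 1) -> np.ndarray:
    v = rng.standard_normal((size, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _point_topology(n: int, element: str = "O") -> Topology:
    """Monatomic tracer topology (one molecule per particle)."""
    return Topology(
        elements=np.array([element] * n, dtype=object),
        masses=np.full(n, 15.999),
        charges=np.zeros(n),
        mol_ids=np.arange(n),
        roles=np.array(["ion"] * n, dtype=object),
    )


def _package(spec: SyntheticSpec, positions: np.ndarray, topology: Topology | None,
             ground_truth: dict) -> SyntheticResult:
    """Wrap continuous positions into the box and assemble the result."""
    box = spec.box
    traj = Trajectory(
        times=spec.times,
        coords=box.wrap(positions),
        box=box,
        topology=topology,
        wrapped=True,
    )
    ground_truth = dict(ground_truth)
    ground_truth["unwrapped"] = positions
    return SyntheticResult(spec=spec, trajectory=traj, topology=topology,
                           ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# translational generators
# ---------------------------------------------------------------------------

def gen_brownian(spec: SyntheticSpec) -> SyntheticResult:
    """Independent Gaussian increments per axis with variance 2·D·dt.

    The ensemble mean-squared displacement is 6·D·t, i.e. the diffusive
    α = 1 reference process.
    """
    D = float(spec.params.get("D", 0.2))
    sigma = np.sqrt(2.0 * D * spec.dt)
    pos = np.empty((spec.n_frames, spec.n_particles, 3))
    for i, rng in enumerate(_particle_rngs(spec)):
        r0 = rng.uniform(0.0, spec.box_length, 3)
        steps = rng.normal(0.0, sigma, (spec.n_frames - 1, 3)) if spec.n_frames > 1 else np.empty((0, 3))
        pos[:, i] = np.vstack([r0, r0 + np.cumsum(steps, axis=0)])
    return _package(spec, pos, _point_topology(spec.n_particles), {"D": D})


def gen_ballistic(spec: SyntheticSpec) -> SyntheticResult:
    """Constant-velocity streaming: r(t) = r(0) + v·t, isotropic directions.

    Speeds are drawn uniformly from ``speed × [0.5, 1.5]`` unless
    ``speed_law == "fixed"``.  The ensemble MSD is ⟨v²⟩·t², the ballistic
    α = 2 reference.
    """
    speed = float(spec.params.get("speed", 1.0))
    law = spec.params.get("speed_law", "uniform")
    t = spec.times
    pos = np.empty((spec.n_frames, spec.n_particles, 3))
    velocities = np.empty((spec.n_particles, 3))
    for i, rng in enumerate(_particle_rngs(spec)):
        r0 = rng.uniform(0.0, spec.box_length, 3)
        s = speed if law == "fixed" else rng.uniform(0.5 * speed, 1.5 * speed)
        v = s * _uniform_sphere(rng)[0]
        velocities[i] = v
        pos[:, i] = r0 + np.outer(t, v)
    if np.max(np.abs(velocities)) * spec.dt >= spec.box_length / 2:
        raise SyntheticSpecError("per-frame ballistic step >= L/2; reduce speed or dt")
    return _package(spec, pos, _point_topology(spec.n_particles),
                    {"velocities": velocities, "mean_sq_speed": float(np.mean(np.sum(velocities**2, axis=1)))})


def gen_levy_hop(spec: SyntheticSpec) -> SyntheticResult:
    """Rest-and-jump motion: exponential waiting times, instantaneous hops.

    Particles sit at a site for an Exp(mean τ_w) waiting time, then jump by a
    drawn length in a uniform random direction.  The default jump law is a
    fixed length ℓ (sharpest van Hove signature); ``jump_law == "pareto"``
    draws Pareto(ℓ, shape) lengths truncated at L/2.  Hop events are logged
    as ground truth.
    """
    ell = float(spec.params.get("hop_length", 8.0))
    tau_w = float(spec.params.get("tau_wait", 10.0))
    jump_law = spec.params.get("jump_law", "fixed")
    pareto_shape = float(spec.params.get("pareto_shape", 2.5))
    L = spec.box_length
    if ell >= L / 2:
        raise SyntheticSpecError(f"hop length {ell} Å >= L/2 = {L / 2} Å breaks unwrapping")
    t_end = spec.times[-1]
    pos = np.empty((spec.n_frames, spec.n_particles, 3))
    hops: list[tuple[int, float, float]] = []
    for i, rng in enumerate(_particle_rngs(spec)):
        r = rng.uniform(0.0, L, 3)
        event_times: list[float] = []
        event_pos: list[np.ndarray] = [r.copy()]
        t_now = 0.0
        if not np.isfinite(tau_w) or tau_w <= 0:
            t_now = np.inf  # tau_wait = 0/inf disables hopping (inf mean wait)
        while t_now < t_end:
            t_now += rng.exponential(tau_w)
            if t_now >= t_end:
                break
            if jump_law == "pareto":
                length = min(ell * (1.0 + rng.pareto(pareto_shape)), L / 2 * 0.999)
            else:
                length = ell
            r = r + length * _uniform_sphere(rng)[0]
            event_times.append(t_now)
            event_pos.append(r.copy())
            hops.append((i, t_now, length))
        # piecewise-constant sampling at the frame times
        idx = np.searchsorted(np.array(event_times), spec.times, side="right")
        pos[:, i] = np.array(event_pos)[idx]
    log = pd.DataFrame(hops, columns=["particle", "time", "length"])
    if len(log):
        log["frame_after"] = np.minimum(
            np.floor(log["time"] / spec.dt).astype(int) + 1, spec.n_frames - 1
        )
    else:
        log["frame_after"] = pd.Series(dtype=int)
    return _package(spec, pos, _point_topology(spec.n_particles),
                    {"hop_log": log, "hop_length": ell, "tau_wait": tau_w})


# ---------------------------------------------------------------------------
# rotational generator
# ---------------------------------------------------------------------------

def _rotor_series(rng: np.random.Generator, n_frames: int, dt: float, d_r: float) -> np.ndarray:
    """Isotropic rotational diffusion of one unit vector (Euler scheme)."""
    u = np.empty((n_frames, 3))
    u[0] = _uniform_sphere(rng)[0]
    if d_r <= 0:
        u[:] = u[0]
        return u
    sigma = np.sqrt(2.0 * d_r * dt)
    xi = rng.standard_normal((n_frames - 1, 3))
    for k in range(1, n_frames):
        g = xi[k - 1]
        g = g - np.dot(g, u[k - 1]) * u[k - 1]  # tangent-plane noise
        v = u[k - 1] + sigma * g
        u[k] = v / np.linalg.norm(v)
    return u


def gen_rotor(spec: SyntheticSpec) -> SyntheticResult:
    """Unit dipole vectors undergoing isotropic rotational diffusion.

    The first-rank orientational correlation is exp(−2·D_r·t) in
    expectation, so the integrated relaxation time is 1/(2·D_r).
    """
    d_r = float(spec.params.get("D_r", 0.025))
    u = np.empty((spec.n_frames, spec.n_particles, 3))
    for i, rng in enumerate(_particle_rngs(spec)):
        u[:, i] = _rotor_series(rng, spec.n_frames, spec.dt, d_r)
    return SyntheticResult(spec=spec, dipoles=u,
                           ground_truth={"D_r": d_r, "tau_R": np.inf if d_r == 0 else 1.0 / (2 * d_r)})


# ---------------------------------------------------------------------------
# hydrogen-bond lattice
# ---------------------------------------------------------------------------

_TETRA = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)


def gen_hb_lattice(
    oo_distance: float = 2.8,
    n_cells: int = 2,
    *,
    periodic: bool = True,
    require_bond_window: bool = True,
) -> SyntheticResult:
    """Ice-like tetrahedral water lattice saturating the H-bond criteria.

    Oxygens sit on a diamond-cubic lattice with nearest-neighbour O–O
    distance ``oo_distance``; each oxygen donates two hydrogens placed on
    donor O–O axes at 1.0 Å from the donor (a uniformly polarised
    ice-rules assignment: every molecule donates 2 and accepts 2).  Under
    periodic boundaries every molecule therefore has exactly 4 hydrogen
    bonds when 1.0 + 2.5 > O–O and O–O < 3.5 Å; with ``periodic=False``
    the cluster is padded and surface molecules lose coordination.
    """
    if require_bond_window and not (2.5 < oo_distance < 3.5):
        raise SyntheticSpecError(
            f"O-O distance {oo_distance} Å outside the (2.5, 3.5) Å hydrogen-bond window"
        )
    a = 4.0 * oo_distance / np.sqrt(3.0)  # cubic cell edge
    fcc = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    cells = np.array([[i, j, k] for i in range(n_cells) for j in range(n_cells) for k in range(n_cells)])
    site_a = a * (cells[:, None, :] + fcc[None, :, :]).reshape(-1, 3)
    offsets = (a / 4.0) * _TETRA
    site_b = site_a + offsets[0]
    o_pos = np.vstack([site_a, site_b])
    n_a = len(site_a)
    # donation directions: A sublattice along +d1,+d2; B sublattice along −d3,−d4
    h_list = []
    for k in range(len(o_pos)):
        dirs = (offsets[:2] if k < n_a else -offsets[2:])
        for d in dirs:
            h_list.append(o_pos[k] + 1.0 * d / np.linalg.norm(d))
    h_pos = np.array(h_list)
    n_w = len(o_pos)
    coords = np.empty((3 * n_w, 3))
    coords[0::3] = o_pos
    coords[1::3] = h_pos[0::2]
    coords[2::3] = h_pos[1::2]
    if periodic:
        box = Box.cubic(a * n_cells)
        coords = box.wrap(coords)
    else:
        pad = a
        coords = coords - coords.min(axis=0) + pad
        box = Box.cubic(float(coords.max() + pad))
    topology = water_topology(n_w)
    traj = Trajectory(times=np.array([0.0]), coords=coords[None], box=box,
                      topology=topology, wrapped=True)
    spec = SyntheticSpec(kind="hb_lattice", n_particles=n_w, n_frames=1, dt=1.0,
                         box_length=float(box.lengths[0]), seed=0,
                         params={"oo_distance": oo_distance, "n_cells": n_cells,
                                 "periodic": periodic})
    interior = _lattice_interior(o_pos, oo_distance) if not periodic else np.ones(n_w, bool)
    return SyntheticResult(spec=spec, trajectory=traj, topology=topology,
                           ground_truth={"interior_mask": interior, "lattice_a": a})


def _lattice_interior(o_pos: np.ndarray, oo: float) -> np.ndarray:
    """Molecules with a full set of 4 lattice neighbours (non-periodic case)."""
    from scipy.spatial import cKDTree

    tree = cKDTree(o_pos)
    counts = np.array([len(tree.query_ball_point(p, oo * 1.05)) - 1 for p in o_pos])
    return counts == 4


# ---------------------------------------------------------------------------
# shell-exchange generator
# ---------------------------------------------------------------------------

def gen_shell_exchange(spec: SyntheticSpec) -> SyntheticResult:
    """Two-state telegraph kinetics in/out of a spherical shell region.

    Each particle carries an in/out state with escape rate ``k_out`` and
    re-entry rate ``k_in`` (0 disables re-entry); it is a rigid water placed
    uniformly inside the region (min distance to the central dummy solute
    atom < ``radius``) when in, and in an outer shell when out.  Optional
    brief excursions (``excursion_duration`` ps at ``excursion_rate`` per ps
    per in-state particle) are injected afterwards to exercise the t*
    tolerance of residence statistics.  The exact state series is returned
    as ground truth.
    """
    k_out = float(spec.params.get("k_out", 0.05))
    k_in = float(spec.params.get("k_in", 0.0))
    radius = float(spec.params.get("radius", 4.0))
    exc_dur = float(spec.params.get("excursion_duration", 0.0))
    exc_rate = float(spec.params.get("excursion_rate", 0.0))
    L = spec.box_length
    if radius * 2 >= L:
        raise SyntheticSpecError("shell radius too large for the box")
    n, F, dt = spec.n_particles, spec.n_frames, spec.dt
    t_end = (F - 1) * dt
    frame_times = spec.times
    states = np.empty((F, n), dtype=bool)
    for i, rng in enumerate(_particle_rngs(spec)):
        # alternate exponential holding times (start inside) until past t_end
        switch_times = []
        t_now, inside = 0.0, True
        while t_now <= t_end:
            rate = k_out if inside else k_in
            if rate <= 0:
                break
            t_now += rng.exponential(1.0 / rate)
            switch_times.append(t_now)
            inside = not inside
        n_switches = np.searchsorted(np.array(switch_times), frame_times, side="right")
        col = (n_switches % 2) == 0
        # inject brief excursions into in-runs (ground truth keeps the flips)
        if exc_dur > 0 and exc_rate > 0:
            d_frames = max(1, int(round(exc_dur / dt)))
            hits = np.flatnonzero(rng.random(F) < exc_rate * dt)
            for f in hits:
                if 1 <= f < F - d_frames - 1 and col[f - 1] and np.all(col[f : f + d_frames + 1]):
                    col[f : f + d_frames] = False
        states[:, i] = col
    # positions consistent with the state series
    pos_o = np.empty((F, n, 3))
    center = np.full(3, L / 2.0)
    for i, rng in enumerate(_particle_rngs(spec, stream=1)):
        r_in = radius * 0.9 * rng.random((F,)) ** (1 / 3)
        r_out = radius * 1.5 + (L / 2 * 0.8 - radius * 1.5) * rng.random((F,))
        dirs = _uniform_sphere(rng, F)
        r = np.where(states[:, i], r_in, r_out)
        pos_o[:, i] = center + dirs * r[:, None]
    coords, topology = _waters_with_solute(pos_o, center[None, :])
    traj = Trajectory(times=spec.times, coords=spec.box.wrap(coords), box=spec.box,
                      topology=topology, wrapped=True)
    return SyntheticResult(spec=spec, trajectory=traj, topology=topology,
                           ground_truth={"states": states, "k_out": k_out, "k_in": k_in,
                                         "radius": radius})


def _rigid_water(o: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """O,H,H coordinates of a rigid water whose dipole axis is ``axis``."""
    o = np.asarray(o, float)
    hh = _rigid_water_h(np.asarray(axis, float))
    return np.stack([o, o + hh[0], o + hh[1]])


def _rigid_water_h(axes: np.ndarray) -> np.ndarray:
    """H offsets (2, ..., 3) from O for dipole axes of any leading shape."""
    axes = axes / np.linalg.norm(axes, axis=-1, keepdims=True)
    ref = np.zeros_like(axes)
    use_x = np.abs(axes[..., 0]) < 0.9
    ref[..., 0] = np.where(use_x, 1.0, 0.0)
    ref[..., 1] = np.where(use_x, 0.0, 1.0)
    perp = np.cross(axes, ref)
    perp /= np.linalg.norm(perp, axis=-1, keepdims=True)
    half = np.deg2rad(HOH_ANGLE_DEG / 2.0)
    h1 = OH_LENGTH * (np.cos(half) * axes + np.sin(half) * perp)
    h2 = OH_LENGTH * (np.cos(half) * axes - np.sin(half) * perp)
    return np.stack([h1, h2])


def _waters_with_solute(pos_o: np.ndarray, solute_pos: np.ndarray,
                        orientations: np.ndarray | None = None,
                        solute_elements: np.ndarray | None = None) -> tuple[np.ndarray, Topology]:
    """Assemble (frames, atoms, 3) coordinates: solute atoms then rigid waters."""
    F, n = pos_o.shape[:2]
    n_s = len(solute_pos)
    coords = np.empty((F, n_s + 3 * n, 3))
    coords[:, :n_s] = solute_pos[None, :, :]
    if orientations is None:
        axes = np.broadcast_to(np.array([0.0, 0.0, 1.0]), (F, n, 3))
    else:
        axes = orientations
    hh = _rigid_water_h(axes)  # (2, F, n, 3)
    coords[:, n_s + 0 :: 3] = pos_o
    coords[:, n_s + 1 :: 3] = pos_o + hh[0]
    coords[:, n_s + 2 :: 3] = pos_o + hh[1]
    wat = water_topology(n, first_mol_id=1)
    if solute_elements is None:
        solute_elements = np.array(["C"] * n_s, dtype=object)
    topology = Topology(
        elements=np.concatenate([np.asarray(solute_elements, dtype=object), wat.elements]),
        masses=np.concatenate([np.full(n_s, 12.011), wat.masses]),
        charges=np.concatenate([np.zeros(n_s), wat.charges]),
        mol_ids=np.concatenate([np.zeros(n_s, dtype=int), wat.mol_ids]),
        roles=np.concatenate([np.array(["solute"] * n_s, dtype=object), wat.roles]),
        groups={"SITE": np.array([0])},
    )
    return coords, topology


def gen_composite(spec: SyntheticSpec) -> SyntheticResult:
    """Brownian rigid waters with rotational diffusion around a dummy solute.

    The end-to-end pipeline fixture: a small rigid solute cluster at the box
    centre, waters whose oxygens follow Brownian paths (D) and whose dipole
    axes follow rotational diffusion (D_r).
    """
    D = float(spec.params.get("D", 0.2))
    d_r = float(spec.params.get("D_r", 0.1))
    L = spec.box_length
    n, F, dt = spec.n_particles, spec.n_frames, spec.dt
    sigma = np.sqrt(2.0 * D * dt)
    pos_o = np.empty((F, n, 3))
    orient = np.empty((F, n, 3))
    for i, rng in enumerate(_particle_rngs(spec)):
        r0 = rng.uniform(0.0, L, 3)
        steps = rng.normal(0.0, sigma, (F - 1, 3)) if F > 1 else np.empty((0, 3))
        pos_o[:, i] = np.vstack([r0, r0 + np.cumsum(steps, axis=0)])
        orient[:, i] = _rotor_series(rng, F, dt, d_r)
    center = np.full(3, L / 2.0)
    # small rigid cross of solute atoms (2 Å arms); two polar tips so
    # water-solute hydrogen bonds are possible
    arms = np.array([[0, 0, 0], [2, 0, 0], [-2, 0, 0], [0, 2, 0], [0, -2, 0], [0, 0, 2], [0, 0, -2]], float)
    elements = np.array(["C", "N", "O", "C", "C", "C", "C"], dtype=object)
    coords, topology = _waters_with_solute(pos_o, center + arms, orientations=orient,
                                           solute_elements=elements)
    traj = Trajectory(times=spec.times, coords=spec.box.wrap(coords), box=spec.box,
                      topology=topology, wrapped=True)
    return SyntheticResult(spec=spec, trajectory=traj, topology=topology,
                           ground_truth={"D": D, "D_r": d_r, "unwrapped_o": pos_o,
                                         "orientations": orient})


_GENERATORS = {
    "brownian": gen_brownian,
    "ballistic": gen_ballistic,
    "levy_hop": gen_levy_hop,
    "rotor": gen_rotor,
    "shell_exchange": gen_shell_exchange,
    "composite": gen_composite,
}


def generate(spec: SyntheticSpec) -> SyntheticResult:
    """Dispatch on ``spec.kind`` (``hb_lattice`` has its own constructor)."""
    if spec.kind == "hb_lattice":
        return gen_hb_lattice(
            oo_distance=float(spec.params.get("oo_distance", 2.8)),
            n_cells=int(spec.params.get("n_cells", 2)),
            periodic=bool(spec.params.get("periodic", True)),
        )
    return _GENERATORS[spec.kind](spec)


def write_synthetic(result: SyntheticResult, outdir: str | Path, *, stem: str = "synthetic") -> None:
    """Write trajectory (XYZ), spec sidecar (YAML) and ground-truth tables (CSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / f"{stem}.spec.yaml").open("w") as fh:
        yaml.safe_dump(result.spec.to_dict(), fh)
    if result.trajectory is not None:
        write_xyz(result.trajectory, outdir / f"{stem}.xyz")
    if result.dipoles is not None:
        np.savetxt(outdir / f"{stem}.dipoles.csv",
                   result.dipoles.reshape(result.dipoles.shape[0], -1), delimiter=",")
    for key, value in result.ground_truth.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(outdir / f"{stem}.{key}.csv", index=False)
        elif isinstance(value, np.ndarray) and value.ndim == 2:
            np.savetxt(outdir / f"{stem}.{key}.csv", np.asarray(value, float), delimiter=",")
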