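"""Trajectory containers, readers/writers and periodic-geometry primitives.

Everything downstream (hydration layers, hydrogen bonds, MSD, correlation
functions) consumes the :class:`Trajectory` produced here.  Units are fixed
package-wide: coordinates in Å, times in ps, masses in amu, charges in e.

Only orthorhombic periodic boxes are supported; a cubic box is the common
case.  Coordinates are stored *wrapped* into ``[0, L)``; :func:`unwrap`
produces the continuous coordinates needed for displacement statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Box",
    "Topology",
    "Frame",
    "Trajectory",
    "TrajectoryFormatError",
    "UndersamplingError",
    "read_trajectory",
    "read_xyz",
    "write_xyz",
    "read_dlpoly_history",
    "topology_from_pdb",
    "water_topology",
    "unwrap",
    "rewrap",
    "minimum_image_displacement",
    "minimum_image_distance",
    "water_com",
]


class TrajectoryFormatError(ValueError):
    """File contents inconsistent with the declared format or topology."""


class UndersamplingError(ValueError):
    """Inter-frame displacement too large for unambiguous unwrapping."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box with edge lengths in Å."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        if not np.all(lengths > 0):
            raise ValueError(f"box lengths must be positive, got {lengths}")
        object.__setattr__(self, "lengths", lengths)

    @classmethod
    def cubic(cls, edge: float) -> "Box":
        return cls(np.full(3, float(edge)))

    def wrap(self, coords: np.ndarray) -> np.ndarray:
        """Map coordinates into ``[0, L)`` per axis."""
        L = self.lengths
        return np.mod(coords, L)

    def min_image(self, disp: np.ndarray) -> np.ndarray:
        """Minimum-image convention applied to displacement vectors."""
        L = self.lengths
        return disp - L * np.round(disp / L)


# role labels used throughout
ROLE_SOLUTE = "solute"
ROLE_WATER_O = "water-O"
ROLE_WATER_H = "water-H"
ROLE_ION = "ion"

_WATER_ROLES = (ROLE_WATER_O, ROLE_WATER_H)


@dataclass
class Topology:
    """Static per-atom metadata plus named solute groups.

    Parameters
    ----------
    elements, masses, charges, mol_ids, roles
        Per-atom arrays of equal length. ``roles`` entries are one of
        ``"solute"``, ``"water-O"``, ``"water-H"``, ``"ion"``.
    groups
        Named sets of atom indices (e.g. ``{"NH3": [...]}``) used for
        site-resolved selections around specific solute moieties.
    """

    elements: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    mol_ids: np.ndarray
    roles: np.ndarray
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        self.roles = np.asarray(self.roles, dtype=object)
        n = len(self.elements)
        for name in ("masses", "charges", "mol_ids", "roles"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"topology field {name!r} length mismatch")
        self.groups = {k: np.asarray(v, dtype=int) for k, v in self.groups.items()}
        for name, idx in self.groups.items():
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"group {name!r} references atoms outside topology")
        self._validate_waters()

    def _validate_waters(self) -> None:
        water_mask = np.isin(self.roles, _WATER_ROLES)
        for mol in np.unique(self.mol_ids[water_mask]):
            sel = self.mol_ids == mol
            n_o = int(np.sum(self.roles[sel] == ROLE_WATER_O))
            n_h = int(np.sum(self.roles[sel] == ROLE_WATER_H))
            if (n_o, n_h) != (1, 2):
                raise ValueError(
                    f"water molecule {mol} has {n_o} O and {n_h} H (expected 1 and 2)"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def solute_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ROLE_SOLUTE)

    @property
    def water_mol_ids(self) -> np.ndarray:
        """Sorted molecule-ids of the water molecules."""
        return np.unique(self.mol_ids[self.roles == ROLE_WATER_O])

    @property
    def n_waters(self) -> int:
        return len(self.water_mol_ids)

    @property
    def water_oxygen_indices(self) -> np.ndarray:
        """One oxygen atom index per water, ordered by molecule-id."""
        o_idx = np.flatnonzero(self.roles == ROLE_WATER_O)
        order = np.argsort(self.mol_ids[o_idx], kind="stable")
        return o_idx[order]

    @property
    def water_hydrogen_indices(self) -> np.ndarray:
        """(n_waters, 2) hydrogen atom indices aligned with water order."""
        h_idx = np.flatnonzero(self.roles == ROLE_WATER_H)
        mols = self.water_mol_ids
        out = np.empty((len(mols), 2), dtype=int)
        mol_of_h = self.mol_ids[h_idx]
        for i, mol in enumerate(mols):
            out[i] = h_idx[mol_of_h == mol]
        return out


@dataclass
class Frame:
    """A single snapshot: wrapped coordinates plus time and box."""

    time: float
    coords: np.ndarray
    box: Box | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("frame coordinates must have shape (n_atoms, 3)")


@dataclass
class Trajectory:
    """Time-ordered frames with a constant topology and orthorhombic box.

    ``coords`` has shape ``(n_frames, n_atoms, 3)``.  ``wrapped`` records
    whether coordinates are folded into the box or continuous (unwrapped).
    """

    times: np.ndarray
    coords: np.ndarray
    box: Box | None = None
    topology: Topology | None = None
    wrapped: bool = True
    dt_rtol: float = 1e-6

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times and coords disagree on frame count")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise TrajectoryFormatError("frame times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=self.dt_rtol, atol=0):
                raise TrajectoryFormatError("non-uniform timestep between frames")
        if self.topology is not None and self.topology.n_atoms != self.coords.shape[1]:
            raise TrajectoryFormatError(
                f"coordinate count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Uniform frame interval in ps (0 for single-frame trajectories)."""
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), coords=self.coords[i], box=self.box)


# ---------------------------------------------------------------------------
# periodic-geometry primitives
# ---------------------------------------------------------------------------

def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """Minimum-image displacement vector(s) ``b - a``; broadcasts."""
    return box.min_image(np.asarray(b, float) - np.asarray(a, float))


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """Smallest periodic-image distance between points; broadcasts.

    The result lies in ``[0, sqrt(3)·max(L)/2]`` for an orthorhombic box.
    """
    d = minimum_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)


def unwrap(trajectory: Trajectory) -> Trajectory:
    """Remove periodic box jumps, producing continuous coordinates.

    Requires sampling fine enough that every atom moves less than half a box
    edge between consecutive frames; a (near-)half-box inter-frame jump is
    ambiguous and raises :class:`UndersamplingError` naming atom and frame.
    """
    if trajectory.box is None:
        raise ValueError("unwrap requires a periodic box")
    if not trajectory.wrapped:
        return trajectory
    L = trajectory.box.lengths
    disp = np.diff(trajectory.coords, axis=0)
    disp = trajectory.box.min_image(disp)
    # |min-image disp| == L/2 (within rounding) means the true jump is ambiguous
    bad = np.abs(disp) >= (L / 2) * (1 - 1e-9)
    if np.any(bad):
        f, a, _ = np.argwhere(bad)[0]
        raise UndersamplingError(
            f"atom {a} moves >= L/2 between frames {f} and {f + 1}; "
            "trajectory is undersampled for unwrapping"
        )
    coords = np.concatenate(
        [trajectory.coords[:1], trajectory.coords[:1] + np.cumsum(disp, axis=0)]
    )
    return Trajectory(
        times=trajectory.times,
        coords=coords,
        box=trajectory.box,
        topology=trajectory.topology,
        wrapped=False,
    )


def rewrap(trajectory: Trajectory) -> Trajectory:
    """Fold (unwrapped) coordinates back into ``[0, L)``."""
    if trajectory.box is None:
        raise ValueError("rewrap requires a periodic box")
    return Trajectory(
        times=trajectory.times,
        coords=trajectory.box.wrap(trajectory.coords),
        box=trajectory.box,
        topology=trajectory.topology,
        wrapped=True,
    )


def water_com(trajectory: Trajectory) -> np.ndarray:
    """Mass-weighted water centres of mass, shape ``(n_frames, n_waters, 3)``.

    Coordinates must be unwrapped first if the result feeds displacement
    statistics, otherwise the O/H images may straddle the box.
    """
    top = trajectory.topology
    if top is None:
        raise ValueError("water_com requires a topology")
    o_idx = top.water_oxygen_indices
    h_idx = top.water_hydrogen_indices
    m_o = top.masses[o_idx][None, :, None]
    m_h1 = top.masses[h_idx[:, 0]][None, :, None]
    m_h2 = top.masses[h_idx[:, 1]][None, :, None]
    r_o = trajectory.coords[:, o_idx]
    r_h1 = trajectory.coords[:, h_idx[:, 0]]
    r_h2 = trajectory.coords[:, h_idx[:, 1]]
    if trajectory.wrapped and trajectory.box is not None:
        # keep each molecule whole relative to its oxygen
        r_h1 = r_o + trajectory.box.min_image(r_h1 - r_o)
        r_h2 = r_o + trajectory.box.min_image(r_h2 - r_o)
    total = m_o + m_h1 + m_h2
    return (m_o * r_o + m_h1 * r_h1 + m_h2 * r_h2) / total


# ---------------------------------------------------------------------------
# topology constructors
# ---------------------------------------------------------------------------

def water_topology(n_waters: int, *, first_mol_id: int = 0) -> Topology:
    """Pure-water topology: O, H, H per molecule with common point charges."""
    elements = np.tile(np.array(["O", "H", "H"], dtype=object), n_waters)
    masses = np.tile([15.999, 1.008, 1.008], n_waters)
    charges = np.tile([-0.834, 0.417, 0.417], n_waters)
    mol_ids = np.repeat(np.arange(n_waters) + first_mol_id, 3)
    roles = np.tile(np.array([ROLE_WATER_O, ROLE_WATER_H, ROLE_WATER_H], dtype=object), n_waters)
    return Topology(elements, masses, charges, mol_ids, roles)


def topology_from_pdb(path: str | Path, *, water_resnames: tuple[str, ...] = ("HOH", "SOL", "WAT", "TIP4", "SPC")) -> Topology:
    """Bootstrap a topology (elements, residues, roles) from a PDB file.

    Waters are recognised by residue name; every other residue is labelled
    solute.  Charges default to zero (PDB carries none) and masses come from
    the element guesser, so dipole work needs charges filled in afterwards.
    """
    import MDAnalysis as mda
    from MDAnalysis.topology.guessers import guess_masses, guess_types

    u = mda.Universe(str(path))
    try:
        elements = u.atoms.elements
    except Exception:
        elements = guess_types(u.atoms.names)
    masses = guess_masses(elements)
    resnames = u.atoms.resnames
    resids = u.atoms.resids
    roles = np.empty(len(elements), dtype=object)
    water = np.isin(resnames, water_resnames)
    roles[~water] = ROLE_SOLUTE
    roles[water & (np.char.upper(elements.astype(str)) == "O")] = ROLE_WATER_O
    roles[water & (np.char.upper(elements.astype(str)) == "H")] = ROLE_WATER_H
    return Topology(
        elements=elements.astype(object),
        masses=masses,
        charges=np.zeros(len(elements)),
        mol_ids=resids.astype(int),
        roles=roles,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path, *, dt: float = 1.0, topology: Topology | None = None) -> Trajectory:
    """Read a multi-frame XYZ file.

    The comment line may carry metadata as ``t= <ps> box= Lx Ly Lz``; a bare
    triple of numbers is read as box lengths.  Frames without a time stamp
    get ``i * dt``.  Shape-only analyses may omit the box; periodic analyses
    will then fail loudly downstream.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    times: list[float] = []
    box: Box | None = None
    with path.open() as fh:
        lines = fh.read().split("\n")
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        try:
            n_atoms = int(line)
        except ValueError as err:
            raise TrajectoryFormatError(f"{path}: expected atom count at line {i + 1}") from err
        comment = lines[i + 1] if i + 1 < n_lines else ""
        t, frame_box = _parse_xyz_comment(comment)
        if frame_box is not None:
            box = frame_box
        times.append(t if t is not None else len(frames) * dt)
        block = lines[i + 2 : i + 2 + n_atoms]
        if len(block) < n_atoms:
            raise TrajectoryFormatError(f"{path}: truncated frame at line {i + 1}")
        coords = np.empty((n_atoms, 3))
        for j, atom_line in enumerate(block):
            parts = atom_line.split()
            if len(parts) < 4:
                raise TrajectoryFormatError(f"{path}: malformed atom line {i + 3 + j}")
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        i += 2 + n_atoms
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    coords = np.stack(frames)
    if topology is not None and topology.n_atoms != coords.shape[1]:
        raise TrajectoryFormatError(
            f"{path}: file has {coords.shape[1]} atoms but topology declares {topology.n_atoms}"
        )
    return Trajectory(times=np.array(times), coords=coords, box=box, topology=topology)


def _parse_xyz_comment(comment: str) -> tuple[float | None, Box | None]:
    tokens = comment.split()
    t: float | None = None
    box: Box | None = None
    if "t=" in tokens:
        t = float(tokens[tokens.index("t=") + 1])
    if "box=" in tokens:
        k = tokens.index("box=")
        box = Box(np.array([float(x) for x in tokens[k + 1 : k + 4]]))
    elif len(tokens) == 3:
        try:
            box = Box(np.array([float(x) for x in tokens]))
        except ValueError:
            pass
    return t, box


def write_xyz(trajectory: Trajectory, path: str | Path, *, precision: int = 8) -> None:
    """Write XYZ with ``t=``/``box=`` metadata on the comment line."""
    path = Path(path)
    top = trajectory.topology
    elements = (
        top.elements if top is not None else np.array(["X"] * trajectory.n_atoms, dtype=object)
    )
    fmt = f"{{:s}} {{:.{precision}f}} {{:.{precision}f}} {{:.{precision}f}}\n"
    with path.open("w") as fh:
        for i in range(trajectory.n_frames):
            fh.write(f"{trajectory.n_atoms}\n")
            comment = f"t= {trajectory.times[i]:.6f}"
            if trajectory.box is not None:
                L = trajectory.box.lengths
                comment += f" box= {L[0]:.6f} {L[1]:.6f} {L[2]:.6f}"
            fh.write(comment + "\n")
            for el, xyz in zip(elements, trajectory.coords[i]):
                fh.write(fmt.format(str(el), *xyz))


def read_dlpoly_history(path: str | Path, *, topology: Topology | None = None) -> Trajectory:
    """Read a DL_POLY HISTORY file (levcfg 0–2; velocities/forces ignored).

    Coordinates, masses and box come from the MDAnalysis HISTORY reader;
    physical times (ps) are scanned from the ``timestep`` records, which the
    reader does not expose.
    """
    import warnings

    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="HISTORY")
    times, levcfg = _scan_history_records(path)
    if levcfg > 0:
        logger.info("HISTORY %s carries levcfg=%d extra records (velocities/forces); ignored", path, levcfg)
    coords = np.stack([ts.positions.copy() for ts in u.trajectory])
    dims = u.trajectory[0].dimensions
    box = Box(np.array(dims[:3], dtype=float)) if dims is not None else None
    if len(times) != coords.shape[0]:
        times = np.arange(coords.shape[0], dtype=float)
    if topology is not None and topology.n_atoms != coords.shape[1]:
        raise TrajectoryFormatError(
            f"{path}: HISTORY has {coords.shape[1]} atoms but topology declares {topology.n_atoms}"
        )
    traj = Trajectory(times=np.asarray(times, float), coords=coords, box=box, topology=topology)
    if box is not None:
        traj = Trajectory(times=traj.times, coords=box.wrap(coords), box=box, topology=topology)
    return traj


def _scan_history_records(path: Path) -> tuple[np.ndarray, int]:
    times = []
    levcfg = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("timestep"):
                parts = line.split()
                # timestep nstep natms keytrj imcon tstep time
                if len(parts) >= 7:
                    times.append(float(parts[6]))
                if len(parts) >= 4:
                    levcfg = max(levcfg, int(parts[3]))
    return np.array(times, dtype=float), levcfg


_READERS = {
    "xyz": read_xyz,
    "dlpoly-history": read_dlpoly_history,
}


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    topology: Topology | None = None,
    **kwargs,
) -> Trajectory:
    """Read a trajectory, sniffing the format from the file if not declared."""
    path = Path(path)
    if format is None:
        format = _sniff_format(path)
    if format == "pdb":
        raise TrajectoryFormatError(
            "PDB is supported for topology bootstrap only; use topology_from_pdb"
        )
    try:
        reader = _READERS[format]
    except KeyError as err:
        raise TrajectoryFormatError(f"unknown trajectory format {format!r}") from err
    return reader(path, topology=topology, **kwargs)


def _sniff_format(path: Path) -> str:
    with path.open() as fh:
        head = fh.readline()
        second = fh.readline()
    first = head.strip()
    if first.split() and first.split()[0].isdigit() and len(first.split()) == 1:
        return "xyz"
    if second.strip().split()[:1] and "timestep" in (first + second):
        return "dlpoly-history"
    if first.startswith(("ATOM", "HETATM", "HEADER", "CRYST1", "REMARK")):
        return "pdb"
    # HISTORY: arbitrary title line then an integer header record
    try:
        [int(x) for x in second.split()[:3]]
        return "dlpoly-history"
    except (ValueError, IndexError):
        pass
    raise TrajectoryFormatError(f"cannot sniff trajectory format of {path}")
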