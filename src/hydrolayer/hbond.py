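"""Hydrogen-bond detection, per-layer statistics, lifetimes and density maps.

A hydrogen bond between a donor (H plus its parent heavy atom) and an
acceptor heavy atom exists under the geometric criteria: H···O distance
smaller than 2.5 Å and O···O distance smaller than 3.5 Å (strict
inequalities), with an optional O–H/O–O angle criterion (< 30°) that is off
by default — under the two distance criteria it is fulfilled anyway in
near-linear bonding geometries.  Both water–water ("ww") and water–solute
("ws") bonds are reported.

The intermittent bond-population correlation C_HB(t) is the probability that
a pair bonded at an origin is bonded again a lag t later, irrespective of
intermediate breaks; its double-exponential time constants separate fast
bond break/reform from slow collective rearrangement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .correlate import CorrelationSeries, DoubleExpFit, fit_double_exponential  # noqa: F401
from .shells import LayerAssignment
from .trajectory_io import Box, Frame, Topology, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "HBondCriteria",
    "detect_hbonds",
    "detect_hbonds_trajectory",
    "nhb_per_water",
    "nhb_per_layer",
    "nhb_water_solute",
    "hb_population_correlation",
    "fit_double_exponential",
    "DensityMap",
    "hydration_density_map",
    "write_opendx",
]

_POLAR_ELEMENTS = ("O", "N")


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (distances Å, angle deg, strict <)."""

    ho_max: float = 2.5
    oo_max: float = 3.5
    angle_max: float | None = None  # enable with 30.0

    def __post_init__(self) -> None:
        if self.ho_max <= 0 or self.oo_max <= 0:
            raise ValueError("distance criteria must be positive")
        if self.angle_max is not None and not (0 < self.angle_max <= 90):
            raise ValueError("angle criterion must lie in (0, 90] degrees")


def _donors_acceptors(top: Topology):
    """Donor H atoms with their parent heavy atoms, and acceptor heavy atoms.

    Waters contribute both; solute atoms contribute polar (O/N) acceptors and
    any solute H bonded to a polar parent (nearest heavy atom by index order
    is resolved geometrically at detection time, so here: nearest by chain is
    unknown — parents are matched per frame).
    """
    h_idx = []
    parent = []
    o_idx = top.water_oxygen_indices
    hh = top.water_hydrogen_indices
    for w in range(len(o_idx)):
        for col in range(2):
            h_idx.append(hh[w, col])
            parent.append(o_idx[w])
    solute = top.solute_indices
    elements = np.char.upper(top.elements.astype(str))
    solute_h = solute[elements[solute] == "H"]
    acceptors = np.concatenate([
        o_idx,
        solute[np.isin(elements[solute], _POLAR_ELEMENTS)],
    ]).astype(int)
    return np.array(h_idx, int), np.array(parent, int), solute_h, acceptors


def _pair_distances(a: np.ndarray, b: np.ndarray, box: Box | None) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    if box is not None:
        d = box.min_image(d)
    return np.sqrt(np.sum(d * d, axis=-1))


def detect_hbonds(
    frame: Frame | np.ndarray,
    topology: Topology,
    criteria: HBondCriteria | None = None,
    *,
    box: Box | None = None,
    frame_index: int = 0,
) -> pd.DataFrame:
    """All hydrogen bonds in one frame.

    Returns a record per (donor H, acceptor) pair meeting every enabled
    criterion, with columns ``frame, donor_mol, donor_h, donor_parent,
    acceptor_mol, acceptor_atom, d_ho, d_oo, pair_class`` where pair_class is
    ``"ww"`` (water–water) or ``"ws"`` (water–solute, either direction).
    Minimum-image distances are used when a box is available.
    """
    criteria = criteria or HBondCriteria()
    if isinstance(frame, Frame):
        coords = frame.coords
        box = frame.box if box is None else box
    else:
        coords = np.asarray(frame, float)
    h_idx, parent_idx, solute_h, acceptors = _donors_acceptors(topology)
    # solute donor hydrogens: parent = nearest solute heavy atom in this frame
    if solute_h.size:
        solute = topology.solute_indices
        elements = np.char.upper(topology.elements.astype(str))
        heavy = solute[elements[solute] != "H"]
        if heavy.size:
            d_sh = _pair_distances(coords[solute_h], coords[heavy], box)
            sh_parent = heavy[np.argmin(d_sh, axis=1)]
            polar = np.isin(elements[sh_parent], _POLAR_ELEMENTS)
            h_idx = np.concatenate([h_idx, solute_h[polar]])
            parent_idx = np.concatenate([parent_idx, sh_parent[polar]])
    if h_idx.size == 0 or acceptors.size == 0:
        return _empty_records()
    d_ha = _pair_distances(coords[h_idx], coords[acceptors], box)
    d_pa = _pair_distances(coords[parent_idx], coords[acceptors], box)
    mask = (d_ha < criteria.ho_max) & (d_pa < criteria.oo_max)
    same_mol = topology.mol_ids[h_idx][:, None] == topology.mol_ids[acceptors][None, :]
    mask &= ~same_mol
    if criteria.angle_max is not None:
        mask &= _angle_ok(coords, h_idx, parent_idx, acceptors, box, criteria.angle_max)
    di, ai = np.nonzero(mask)
    roles = topology.roles
    donor_is_water = roles[h_idx[di]] == "water-H"
    acceptor_is_water = roles[acceptors[ai]] == "water-O"
    return pd.DataFrame({
        "frame": frame_index,
        "donor_mol": topology.mol_ids[h_idx[di]],
        "donor_h": h_idx[di],
        "donor_parent": parent_idx[di],
        "acceptor_mol": topology.mol_ids[acceptors[ai]],
        "acceptor_atom": acceptors[ai],
        "d_ho": d_ha[di, ai],
        "d_oo": d_pa[di, ai],
        "pair_class": np.where(donor_is_water & acceptor_is_water, "ww", "ws"),
    })


def _angle_ok(coords, h_idx, parent_idx, acceptors, box, angle_max):
    """Angle between the O–H and O–A vectors at the donor, < angle_max deg."""
    v_oh = coords[h_idx] - coords[parent_idx]
    v_oa = coords[acceptors][None, :, :] - coords[parent_idx][:, None, :]
    if box is not None:
        v_oh = box.min_image(v_oh)
        v_oa = box.min_image(v_oa)
    num = np.einsum("ik,ijk->ij", v_oh, v_oa)
    den = np.linalg.norm(v_oh, axis=1)[:, None] * np.linalg.norm(v_oa, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(num / den, -1.0, 1.0)
    return cosang > np.cos(np.deg2rad(angle_max))


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in [
        ("frame", int), ("donor_mol", int), ("donor_h", int), ("donor_parent", int),
        ("acceptor_mol", int), ("acceptor_atom", int), ("d_ho", float),
        ("d_oo", float), ("pair_class", object)]})


def detect_hbonds_trajectory(
    trajectory: Trajectory,
    criteria: HBondCriteria | None = None,
    *,
    frame_stride: int = 1,
) -> pd.DataFrame:
    """Concatenated bond records over (a stride of) all frames."""
    top = trajectory.topology
    if top is None:
        raise ValueError("hydrogen-bond detection requires a topology")
    recs = [
        detect_hbonds(trajectory.coords[f], top, criteria, box=trajectory.box, frame_index=f)
        for f in range(0, trajectory.n_frames, frame_stride)
    ]
    return pd.concat(recs, ignore_index=True)


# ---------------------------------------------------------------------------
# per-layer statistics
# ---------------------------------------------------------------------------

def nhb_per_water(records: pd.DataFrame, topology: Topology,
                  *, pair_class: str = "ww") -> np.ndarray:
    """(n_frames_present, n_waters) HB counts per water, water-water bonds
    counted once for the donor and once for the acceptor molecule."""
    frames = np.sort(records["frame"].unique())
    mols = topology.water_mol_ids
    mol_col = {m: i for i, m in enumerate(mols)}
    out = np.zeros((len(frames), len(mols)))
    fmap = {f: i for i, f in enumerate(frames)}
    sel = records[records["pair_class"] == pair_class]
    for side in ("donor_mol", "acceptor_mol"):
        sub = sel[np.isin(sel[side], mols)]
        for f, m in zip(sub["frame"].to_numpy(), sub[side].to_numpy()):
            out[fmap[f], mol_col[m]] += 1
    return out


def nhb_per_layer(
    trajectory: Trajectory,
    assignment: LayerAssignment,
    criteria: HBondCriteria | None = None,
    *,
    frame_stride: int = 1,
) -> pd.DataFrame:
    """Mean and frame-to-frame standard deviation of n_HB per water, per layer.

    A water's bonds count toward the layer it occupies that frame.  Frames
    where a layer is empty are excluded from that layer's average (logged).
    The standard deviation is that of the per-frame layer means, i.e. the
    fluctuation of the layer's n_HB over time.
    """
    records = detect_hbonds_trajectory(trajectory, criteria, frame_stride=frame_stride)
    frames = list(range(0, trajectory.n_frames, frame_stride))
    counts = np.zeros((len(frames), assignment.n_waters))
    if len(records):
        present = nhb_per_water(records, trajectory.topology)
        fidx = {f: i for i, f in enumerate(np.sort(records["frame"].unique()))}
        for i, f in enumerate(frames):
            if f in fidx:
                counts[i] = present[fidx[f]]
    rows = []
    for k, name in enumerate(assignment.layer_names):
        means = []
        skipped = 0
        for i, f in enumerate(frames):
            in_layer = assignment.labels[f] == k
            if not in_layer.any():
                skipped += 1
                continue
            means.append(counts[i][in_layer].mean())
        if skipped:
            logger.info("layer %s empty in %d of %d frames; excluded", name, skipped, len(frames))
        if means:
            rows.append((name, float(np.mean(means)), float(np.std(means)), len(means)))
        else:
            rows.append((name, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["layer", "nhb_mean", "nhb_sd", "n_frames"])


def nhb_water_solute(
    trajectory: Trajectory,
    assignment: LayerAssignment,
    criteria: HBondCriteria | None = None,
    *,
    layer=0,
    frame_stride: int = 1,
) -> dict[str, float]:
    """Water–solute HB count under both normalisations.

    ``per_water``: bonds per interfacial water (waters resident in ``layer``);
    ``per_polar_site``: bonds per solute polar (O/N) atom.  Both are reported
    because either normalisation is defensible for a surface-hydration count.
    """
    top = trajectory.topology
    records = detect_hbonds_trajectory(trajectory, criteria, frame_stride=frame_stride)
    ws = records[records["pair_class"] == "ws"]
    frames = list(range(0, trajectory.n_frames, frame_stride))
    elements = np.char.upper(top.elements.astype(str))
    solute = top.solute_indices
    n_polar = int(np.isin(elements[solute], _POLAR_ELEMENTS).sum())
    member = assignment.in_layer(layer)
    per_water_frames = []
    per_site_frames = []
    for f in frames:
        n_bonds = int((ws["frame"] == f).sum())
        n_in = int(member[f].sum())
        if n_in:
            per_water_frames.append(n_bonds / n_in)
        if n_polar:
            per_site_frames.append(n_bonds / n_polar)
    return {
        "per_water": float(np.mean(per_water_frames)) if per_water_frames else np.nan,
        "per_polar_site": float(np.mean(per_site_frames)) if per_site_frames else np.nan,
    }


# ---------------------------------------------------------------------------
# bond-population correlation
# ---------------------------------------------------------------------------

def hb_population_correlation(
    trajectory_or_records,
    *,
    criteria: HBondCriteria | None = None,
    pair_class: str = "ww",
    assignment: LayerAssignment | None = None,
    layer=None,
    origin_stride: int = 1,
    max_lag: int | None = None,
    n_frames: int | None = None,
) -> CorrelationSeries:
    """Intermittent bond-population correlation C_HB(t).

    C_HB(t) = ⟨h(0)h(t)⟩/⟨h(0)⟩ over origins and over pairs bonded at the
    origin, where h is 1 when the (unordered) molecule pair shares any
    hydrogen bond.  With ``assignment``/``layer``, a pair contributes from an
    origin only if at least one of its waters is resident there.  C_HB(0)=1.
    """
    if isinstance(trajectory_or_records, Trajectory):
        traj = trajectory_or_records
        records = detect_hbonds_trajectory(traj, criteria)
        F = traj.n_frames
        dt = traj.dt or 1.0
    else:
        records = trajectory_or_records
        if n_frames is None:
            raise ValueError("n_frames required when passing raw records")
        F = n_frames
        dt = 1.0
    sel = records[records["pair_class"] == pair_class]
    if not len(sel):
        raise ValueError("no bonded pairs at any origin")
    lo = np.minimum(sel["donor_mol"], sel["acceptor_mol"]).to_numpy()
    hi = np.maximum(sel["donor_mol"], sel["acceptor_mol"]).to_numpy()
    pair_key = np.stack([lo, hi], axis=1)
    uniq, inverse = np.unique(pair_key, axis=0, return_inverse=True)
    P = len(uniq)
    h = np.zeros((F, P), dtype=bool)
    h[sel["frame"].to_numpy(), inverse] = True
    weight = None
    if assignment is not None and layer is not None:
        member = assignment.in_layer(layer)  # (F, n_waters)
        col = {m: i for i, m in enumerate(assignment.water_mol_ids)}
        weight = np.zeros((F, P), dtype=bool)
        for p, (a, b) in enumerate(uniq):
            w = np.zeros(F, dtype=bool)
            if a in col:
                w |= member[:, col[a]]
            if b in col:
                w |= member[:, col[b]]
            weight[:, p] = w
    L = F - 1 if max_lag is None else min(max_lag, F - 1)
    num = np.zeros(L + 1)
    den = np.zeros(L + 1)
    for lag in range(L + 1):
        t0 = np.arange(0, F - lag, origin_stride)
        h0 = h[t0]
        if weight is not None:
            h0 = h0 & weight[t0]
        num[lag] = np.sum(h0 & h[t0 + lag])
        den[lag] = h0.sum()
    if den[0] == 0:
        raise ValueError("no bonded pairs at any origin")
    values = np.divide(num, den, out=np.full(L + 1, np.nan), where=den > 0)
    return CorrelationSeries(lags=np.arange(L + 1) * dt, values=values,
                             counts=den.astype(np.int64), label=f"C_HB[{pair_class}]")


# ---------------------------------------------------------------------------
# hydration density map
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    """Time-averaged water-oxygen occupancy on a grid in the solute frame."""

    origin: np.ndarray  # Å, corner of the grid
    spacing: float  # Å
    grid: np.ndarray  # (nx, ny, nz) mean occupancy per voxel

    @property
    def integral(self) -> float:
        """Mean number of waters inside the cutoff region."""
        return float(self.grid.sum())


def hydration_density_map(
    trajectory: Trajectory,
    cutoff: float = 4.0,
    spacing: float = 1.0,
    *,
    reference_frame: int = 0,
) -> DensityMap:
    """Average water-number map around the solute.

    Every frame's solute is superposed onto the reference conformation; the
    same rigid transform carries the water oxygens into the solute frame,
    where those within ``cutoff`` of any solute atom are binned on a grid of
    the given ``spacing``.  The grid integral equals the mean water count
    within the cutoff.
    """
    from scipy.spatial.transform import Rotation

    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    top = trajectory.topology
    if top is None or top.solute_indices.size == 0:
        raise ValueError("density map requires solute atoms")
    sol = top.solute_indices
    o_idx = top.water_oxygen_indices
    ref = trajectory.coords[reference_frame, sol]
    ref_c = ref.mean(axis=0)
    lo = ref.min(axis=0) - cutoff - spacing
    hi = ref.max(axis=0) + cutoff + spacing
    shape = np.ceil((hi - lo) / spacing).astype(int)
    grid = np.zeros(shape)
    box = trajectory.box
    for f in range(trajectory.n_frames):
        sol_f = trajectory.coords[f, sol]
        wat_f = trajectory.coords[f, o_idx]
        if box is not None:
            # unfold frame around the solute centroid before the rigid fit
            c = sol_f.mean(axis=0)
            sol_f = c + box.min_image(sol_f - c)
            wat_f = c + box.min_image(wat_f - c)
        a = sol_f - sol_f.mean(axis=0)
        b = ref - ref_c
        rot, _ = Rotation.align_vectors(b, a)
        wat_aligned = rot.apply(wat_f - sol_f.mean(axis=0)) + ref_c
        sol_aligned = rot.apply(a) + ref_c
        d = _pair_distances(wat_aligned, sol_aligned, None)
        keep = wat_aligned[d.min(axis=1) < cutoff]
        if len(keep):
            idx = np.floor((keep - lo) / spacing).astype(int)
            ok = np.all((idx >= 0) & (idx < shape), axis=1)
            np.add.at(grid, tuple(idx[ok].T), 1.0)
    grid /= trajectory.n_frames
    return DensityMap(origin=lo, spacing=spacing, grid=grid)


def write_opendx(density: DensityMap, path: str | Path) -> None:
    """Write the map as an OpenDX scalar grid readable by molecular viewers."""
    g = density.grid
    nx, ny, nz = g.shape
    with Path(path).open("w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.4f} {:.4f} {:.4f}\n".format(*density.origin))
        fh.write(f"delta {density.spacing:.4f} 0 0\n")
        fh.write(f"delta 0 {density.spacing:.4f} 0\n")
        fh.write(f"delta 0 0 {density.spacing:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {g.size} data follows\n")
        flat = g.ravel()
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
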