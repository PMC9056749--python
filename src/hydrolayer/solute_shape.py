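"""Solute structural descriptors: gyration tensor, asphericity, RMSD.

The gyration tensor S is the (mass-weighted) second moment of atomic
positions about the centroid; its eigenvalues λ₁ ≥ λ₂ ≥ λ₃ sum to R_g² and
their anisotropy quantifies the deviation from spherical shape through the
asphericity b = λ₁ − (λ₂ + λ₃)/2.  RMSD against a reference conformation is
computed after optimal rigid-body superposition (proper rotations only) by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .trajectory_io import Topology, Trajectory

__all__ = ["GyrationResult", "ShapeSeries", "AlignmentError", "gyration",
           "asphericity", "superpose", "rmsd_to_reference", "shape_series"]


class AlignmentError(ValueError):
    """Too few / degenerate atoms for a well-defined superposition."""


@dataclass
class GyrationResult:
    r_g: float  # Å
    eigenvalues: np.ndarray  # Å², descending
    long_axis: np.ndarray  # unit eigenvector of the largest eigenvalue
    degenerate: bool = False  # single-atom / zero-extent input


def gyration(coords: np.ndarray, masses: np.ndarray | None = None,
             *, mass_weighted: bool = True) -> GyrationResult:
    """Gyration tensor about the (mass-weighted) centroid.

    Returns R_g = sqrt(λ₁+λ₂+λ₃), the eigenvalues in descending order and
    the long axis (largest-eigenvalue eigenvector).
    """
    x = np.asarray(coords, float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("coords must be (n_atoms, 3)")
    n = len(x)
    if n == 0:
        raise ValueError("no atoms")
    if mass_weighted and masses is not None:
        w = np.asarray(masses, float)
    else:
        w = np.ones(n)
    w = w / w.sum()
    c = w @ x
    d = x - c
    S = np.einsum("i,ij,ik->jk", w, d, d)
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    r_g = float(np.sqrt(vals.sum()))
    return GyrationResult(r_g=r_g, eigenvalues=vals, long_axis=vecs[:, 0],
                          degenerate=(n < 2 or vals[0] < 1e-300))


def asphericity(eigenvalues: np.ndarray) -> tuple[float, float]:
    """Asphericity b = λ₁ − (λ₂ + λ₃)/2 (Å²) and its R_g²-normalised form.

    0 for a sphere-symmetric distribution, b = R_g² (normalised 1) for a rod.
    """
    lam = np.sort(np.asarray(eigenvalues, float))[::-1]
    if lam[0] < 0 or len(lam) != 3:
        raise ValueError("need three non-negative eigenvalues")
    b = float(lam[0] - 0.5 * (lam[1] + lam[2]))
    total = float(lam.sum())
    return b, (b / total if total > 0 else 0.0)


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Optimal proper-rotation + translation of ``mobile`` onto ``reference``.

    Returns the transformed coordinates and the post-fit RMSD.  Reflections
    are excluded (scipy's Kabsch solver returns proper rotations).
    """
    mob = np.asarray(mobile, float)
    ref = np.asarray(reference, float)
    if mob.shape != ref.shape:
        raise ValueError("shape mismatch between mobile and reference")
    if len(mob) < 3:
        raise AlignmentError("need >= 3 atoms for superposition")
    w = np.ones(len(mob)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    c_mob = w @ mob
    c_ref = w @ ref
    a = mob - c_mob
    b = ref - c_ref
    span = np.linalg.matrix_rank(np.einsum("i,ij,ik->jk", w, b, b), tol=1e-10)
    if span < 2:
        raise AlignmentError("reference atoms are (nearly) collinear; rotation ill-defined")
    rot, _ = Rotation.align_vectors(b, a, weights=w)
    moved = rot.apply(a) + c_ref
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - ref) ** 2, axis=1))))
    return moved, rmsd


def rmsd_to_reference(
    trajectory: Trajectory,
    reference_frame: int = 0,
    *,
    atom_indices: np.ndarray | None = None,
    superpose_flag: bool = True,
    mass_weighted: bool = False,
) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference conformation.

    With superposition (default) each frame is optimally aligned first;
    without, only centroids are removed, so residual rotation counts.
    """
    top = trajectory.topology
    if atom_indices is None:
        atom_indices = top.solute_indices if top is not None else np.arange(trajectory.n_atoms)
    if atom_indices.size == 0:
        raise ValueError("no atoms selected for RMSD")
    weights = None
    if mass_weighted and top is not None:
        weights = top.masses[atom_indices]
    ref = trajectory.coords[reference_frame, atom_indices]
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        x = trajectory.coords[f, atom_indices]
        if superpose_flag:
            _, out[f] = superpose(x, ref, weights)
        else:
            w = np.ones(len(x)) if weights is None else np.asarray(weights, float)
            w = w / w.sum()
            a = x - w @ x
            b = ref - w @ ref
            out[f] = float(np.sqrt(np.sum(w * np.sum((a - b) ** 2, axis=1))))
    return out


def shape_series(trajectory: Trajectory, *, mass_weighted: bool = True,
                 superpose_flag: bool = True) -> pd.DataFrame:
    """Per-frame solute shape table: R_g, eigenvalues, asphericity, RMSD.

    Eigenvalues are descending; RMSD is against frame 0 with optimal
    superposition by default.
    """
    top = trajectory.topology
    if top is None:
        raise ValueError("shape_series requires a topology")
    idx = top.solute_indices
    if idx.size < 2:
        raise ValueError("need >= 2 solute atoms")
    masses = top.masses[idx]
    rows = []
    for f in range(trajectory.n_frames):
        g = gyration(trajectory.coords[f, idx], masses, mass_weighted=mass_weighted)
        b, b_norm = asphericity(g.eigenvalues)
        rows.append((trajectory.times[f], g.r_g, *g.eigenvalues, b, b_norm))
    df = pd.DataFrame(rows, columns=["time_ps", "r_g", "lambda1", "lambda2",
                                     "lambda3", "asphericity", "asphericity_norm"])
    df["rmsd"] = rmsd_to_reference(trajectory, superpose_flag=superpose_flag)
    return df
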