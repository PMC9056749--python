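#!/usr/bin/env python
"""Generate the synthetic study systems and their ground-truth sidecars.

Writes, under results/synthetic/: a composite system (Brownian rigid waters
with rotational diffusion around a dummy solute), a ballistic and a Brownian
control ensemble, a rest-and-jump (hop) ensemble, a shell-exchange ensemble
and the hydrogen-bond-saturated tetrahedral lattice.  Every trajectory is
accompanied by its spec YAML and ground-truth tables, so each later analysis
step can be checked against what was actually put in.
"""

from pathlib import Path

from hydrolayer.synthetic_data import SyntheticSpec, generate, write_synthetic

OUT = Path("results/synthetic")
SEED = 2024

SYSTEMS = {
    "composite": SyntheticSpec(kind="composite", n_particles=60, n_frames=400,
                               dt=0.1, box_length=28.0, seed=SEED,
                               params={"D": 0.2, "D_r": 0.1}),
    "ballistic": SyntheticSpec(kind="ballistic", n_particles=100, n_frames=1000,
                               dt=0.1, box_length=50.0, seed=SEED + 1,
                               params={"speed": 1.0}),
    "brownian": SyntheticSpec(kind="brownian", n_particles=200, n_frames=2000,
                              dt=0.1, box_length=50.0, seed=SEED + 2,
                              params={"D": 0.2}),
    "levy_hop": SyntheticSpec(kind="levy_hop", n_particles=300, n_frames=250,
                              dt=0.1, box_length=40.0, seed=SEED + 3,
                              params={"hop_length": 8.0, "tau_wait": 10.0}),
    "shell_exchange": SyntheticSpec(kind="shell_exchange", n_particles=1500,
                                    n_frames=1200, dt=0.1, box_length=40.0,
                                    seed=SEED + 4,
                                    params={"k_out": 0.05, "k_in": 0.0, "radius": 4.0}),
    "hb_lattice": SyntheticSpec(kind="hb_lattice", n_particles=1, n_frames=1,
                                dt=1.0, box_length=1.0, seed=0,
                                params={"oo_distance": 2.8, "n_cells": 2}),
}


PREVIEW_FRAMES = 25  # trajectories are previews; the spec YAML regenerates all
PREVIEW_COLS = 200
MAX_XYZ_ATOMS = 1000  # very large systems keep only spec + ground truth on disk


def _preview(result):
    """Trim trajectory and frame-indexed ground truth for compact output."""
    import numpy as np
    from hydrolayer.synthetic_data import SyntheticResult
    from hydrolayer.trajectory_io import Trajectory

    traj = result.trajectory
    if traj is not None and traj.n_frames > PREVIEW_FRAMES:
        traj = Trajectory(times=traj.times[:PREVIEW_FRAMES],
                          coords=traj.coords[:PREVIEW_FRAMES], box=traj.box,
                          topology=traj.topology, wrapped=traj.wrapped)
    if traj is not None and traj.n_atoms > MAX_XYZ_ATOMS:
        traj = None
    n_frames = result.spec.n_frames
    gt = {}
    for key, value in result.ground_truth.items():
        if isinstance(value, np.ndarray) and value.ndim >= 2 and len(value) == n_frames:
            value = value[:PREVIEW_FRAMES, :PREVIEW_COLS]
        gt[key] = value
    return SyntheticResult(spec=result.spec, trajectory=traj,
                           dipoles=result.dipoles, topology=result.topology,
                           ground_truth=gt)


def main() -> None:
    for name, spec in SYSTEMS.items():
        result = generate(spec)
        write_synthetic(_preview(result), OUT, stem=name)
        traj = result.trajectory
        shape = f"{traj.n_frames} frames x {traj.n_atoms} atoms" if traj else "dipole series"
        print(f"{name:15s} {shape:30s} -> {OUT}/{name}.* "
              f"(first {PREVIEW_FRAMES} frames on disk; spec YAML regenerates all)")
    print(f"\nAll systems and ground truth written under {OUT}/")


if __name__ == "__main__":
    main()
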