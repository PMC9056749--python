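"""Hydration-layer decomposition around the solute.

Each water is assigned, frame by frame, to a distance layer by the minimum
periodic distance from its chosen site (oxygen by default) to any solute
atom.  Default edges are the 4 Å-wide bins 0–4/4–8/8–12/12–16 Å with bulk
beyond the last edge.  Bins are half-open ``[e_k, e_{k+1})``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory_io import Box, Topology, Trajectory

__all__ = ["LayerSpec", "LayerAssignment", "TopologyError", "assign_layers",
           "continuous_membership_mask", "endpoint_membership_mask"]

BULK = "bulk"


class TopologyError(ValueError):
    pass


@dataclass(frozen=True)
class LayerSpec:
    """Strictly increasing layer edges in Å; beyond the last edge is bulk."""

    edges: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0)

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 2:
            raise ValueError("need at least two edges")
        if any(e < 0 for e in edges) or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must be non-negative and strictly increasing")
        object.__setattr__(self, "edges", edges)

    @property
    def labels(self) -> list[str]:
        """Layer names, e.g. ``['0-4 A', '4-8 A', ..., 'bulk']``."""
        names = [f"{a:g}-{b:g} A" for a, b in zip(self.edges, self.edges[1:])]
        return names + [BULK]

    @property
    def n_layers(self) -> int:
        return len(self.edges)  # len-1 bins + bulk

    def classify(self, distances: np.ndarray) -> np.ndarray:
        """Half-open bin index per distance; last index is bulk.

        Distances below the first edge (possible when edges[0] > 0) are
        assigned to bin 0 together with the first layer.
        """
        idx = np.searchsorted(np.asarray(self.edges), distances, side="right") - 1
        return np.clip(idx, 0, len(self.edges) - 1)


@dataclass
class LayerAssignment:
    """Per-frame, per-water minimum solute distance and layer index."""

    spec: LayerSpec
    distances: np.ndarray  # (n_frames, n_waters) Å
    labels: np.ndarray  # (n_frames, n_waters) int layer index
    water_mol_ids: np.ndarray
    water_site: str = "O"

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_waters(self) -> int:
        return self.labels.shape[1]

    @property
    def layer_names(self) -> list[str]:
        return self.spec.labels

    def layer_index(self, layer: int | str) -> int:
        if isinstance(layer, str):
            return self.layer_names.index(layer)
        return int(layer)

    def _layer_indices(self, layer) -> np.ndarray:
        """Normalise a layer or union of layers to an index array."""
        if isinstance(layer, (int, np.integer, str)):
            return np.array([self.layer_index(layer)])
        return np.array([self.layer_index(k) for k in layer])

    def in_layer(self, layer) -> np.ndarray:
        """Boolean (n_frames, n_waters) membership of a layer or layer union."""
        return np.isin(self.labels, self._layer_indices(layer))

    def populations(self) -> pd.DataFrame:
        """Per-frame layer populations; rows are frames, columns layers."""
        n_bins = self.spec.n_layers
        counts = np.stack([(self.labels == k).sum(axis=1) for k in range(n_bins)], axis=1)
        return pd.DataFrame(counts, columns=self.layer_names)

    def to_frame(self, frame_stride: int = 1) -> pd.DataFrame:
        """Tidy per-(frame, water) table: frame, water-id, distance, layer."""
        F, W = self.labels.shape
        sel = np.arange(0, F, frame_stride)
        frames = np.repeat(sel, W)
        waters = np.tile(self.water_mol_ids, len(sel))
        names = np.array(self.layer_names, dtype=object)
        return pd.DataFrame({
            "frame": frames,
            "water": waters,
            "distance": self.distances[sel].ravel(),
            "layer": names[self.labels[sel].ravel()],
        })

    def to_csv(self, path: str | Path, frame_stride: int = 1) -> None:
        self.to_frame(frame_stride).to_csv(path, index=False, float_format="%.4f")


def assign_layers(
    trajectory: Trajectory,
    layer_spec: LayerSpec | None = None,
    *,
    water_site: str = "O",
    topology: Topology | None = None,
) -> LayerAssignment:
    """Assign every water in every frame to a hydration layer.

    ``water_site`` selects the distance reference on the water: ``"O"``
    (atomic criterion, the default) or ``"com"`` (mass-weighted centre).
    """
    top = topology or trajectory.topology
    if top is None:
        raise TopologyError("layer assignment requires a topology")
    if trajectory.box is None:
        raise TopologyError("layer assignment requires a periodic box")
    solute = top.solute_indices
    if solute.size == 0:
        raise TopologyError("topology declares no solute atoms")
    if water_site == "O":
        sites = trajectory.coords[:, top.water_oxygen_indices]
    elif water_site == "com":
        from .trajectory_io import water_com
        sites = water_com(trajectory)
    else:
        raise ValueError(f"unknown water_site {water_site!r}")
    spec = layer_spec or LayerSpec()
    dists = _min_solute_distance(sites, trajectory.coords[:, solute], trajectory.box)
    labels = spec.classify(dists)
    return LayerAssignment(spec=spec, distances=dists, labels=labels,
                           water_mol_ids=top.water_mol_ids, water_site=water_site)


def _min_solute_distance(sites: np.ndarray, solute: np.ndarray, box: Box) -> np.ndarray:
    """Per-frame min over solute atoms of the minimum-image distance."""
    F = sites.shape[0]
    out = np.empty(sites.shape[:2])
    for f in range(F):  # frame loop keeps the (W, S, 3) temporary small
        d = sites[f][:, None, :] - solute[f][None, :, :]
        d = box.min_image(d)
        out[f] = np.sqrt(np.sum(d * d, axis=-1)).min(axis=1)
    return out


def continuous_membership_mask(
    assignment: LayerAssignment, layer, t0_index: int, lag: int
) -> np.ndarray:
    """True per water iff it stays in ``layer`` at every frame t0 … t0+lag.

    ``layer`` may be a single layer (index or name) or a union of layers.
    """
    if t0_index + lag >= assignment.n_frames:
        raise IndexError("t0_index + lag beyond trajectory")
    member = assignment.in_layer(layer)
    return np.all(member[t0_index : t0_index + lag + 1], axis=0)


def endpoint_membership_mask(
    assignment: LayerAssignment, layer, t0_index: int, lag: int
) -> np.ndarray:
    """True per water iff it is in ``layer`` at both t0 and t0+lag only."""
    if t0_index + lag >= assignment.n_frames:
        raise IndexError("t0_index + lag beyond trajectory")
    member = assignment.in_layer(layer)
    return member[t0_index] & member[t0_index + lag]
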