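"""Rotational dynamics of water: dipole autocorrelation and relaxation times.

The water dipole unit vector u(t) is built from partial charges and geometry;
its first-rank orientational correlation C(t) = ⟨u(t0)·u(t0+t)⟩ is averaged
over origins and over the molecules resident in a layer (or near a named
solute site) *at the origin frame* — origin-resident selection, deliberately
not continuous residence, so slow relaxations are not truncated by fast
exchange out of a thin shell.  The relaxation time τ_R is the time integral
of C(t), evaluated by trapezoid plus an exponential-tail extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlate import CorrelationSeries
from .shells import LayerAssignment
from .trajectory_io import Topology, Trajectory

__all__ = [
    "DivergenceError",
    "RelaxationTime",
    "RotationalResult",
    "compute_dipoles",
    "dipole_acf",
    "relaxation_time",
    "site_selection_mask",
    "site_resolved_tau",
    "layer_relaxation",
]


class DivergenceError(RuntimeError):
    """Correlation has not decayed enough for a finite time integral."""


def compute_dipoles(trajectory: Trajectory, *, rank_normalize: bool = True) -> np.ndarray:
    """Per-water unit dipole vectors, shape (n_frames, n_waters, 3).

    μ_i = Σ q_a (r_a − r_O) over the three water sites; with a wrapped
    trajectory the hydrogens are unfolded relative to their oxygen first.
    """
    top = trajectory.topology
    if top is None:
        raise ValueError("dipoles require a topology with charges")
    o_idx = top.water_oxygen_indices
    h_idx = top.water_hydrogen_indices
    r_o = trajectory.coords[:, o_idx]
    mu = np.zeros_like(r_o)
    for col in range(2):
        idx = h_idx[:, col]
        r_h = trajectory.coords[:, idx]
        d = r_h - r_o
        if trajectory.wrapped and trajectory.box is not None:
            d = trajectory.box.min_image(d)
        mu += top.charges[idx][None, :, None] * d
    norm = np.linalg.norm(mu, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("zero dipole moment encountered; check water charges")
    return mu / norm


def dipole_acf(
    dipoles: np.ndarray,
    times: np.ndarray,
    *,
    member: np.ndarray | None = None,
    origin_stride: int = 1,
    max_lag: int | None = None,
    label: str = "",
) -> CorrelationSeries:
    """First-rank orientational correlation C(t) = ⟨u(t0)·u(t0+t)⟩.

    ``member`` (n_frames, n_molecules) selects contributors by membership at
    the origin frame only.  With stride 1 the origin average runs through an
    FFT cross-correlation; otherwise a strided per-lag loop is used.
    """
    u = np.asarray(dipoles, float)
    times = np.asarray(times, float)
    F, N = u.shape[:2]
    L = F - 1 if max_lag is None else min(max_lag, F - 1)
    if member is not None:
        member = np.asarray(member, bool)
        if member.shape != (F, N):
            raise ValueError("member mask shape must match (n_frames, n_molecules)")
        if not member.any():
            raise ValueError("empty selection at every origin")
    dt = float(times[1] - times[0]) if F > 1 else 1.0
    if origin_stride == 1:
        num, cnt = _acf_fft(u, member, L)
    else:
        num = np.zeros(L + 1)
        cnt = np.zeros(L + 1, dtype=np.int64)
        for lag in range(L + 1):
            t0 = np.arange(0, F - lag, origin_stride)
            dots = np.einsum("onk,onk->on", u[t0], u[t0 + lag])
            if member is not None:
                w = member[t0]
                num[lag] = dots[w].sum()
                cnt[lag] = w.sum()
            else:
                num[lag] = dots.sum()
                cnt[lag] = dots.size
    if cnt[0] == 0:
        raise ValueError("empty selection at every origin")
    values = np.divide(num, cnt, out=np.full(L + 1, np.nan), where=cnt > 0)
    values = values / values[0]  # exact C(0) = 1 (unit vectors make this a no-op)
    return CorrelationSeries(lags=np.arange(L + 1) * dt, values=values, counts=cnt, label=label)


def _acf_fft(u: np.ndarray, member: np.ndarray | None, L: int):
    """Origin sums Σ_t0 (m·u)(t0)·u(t0+t) per lag via FFT cross-correlation."""
    F, N = u.shape[:2]
    n_fft = 1 << (2 * F - 1).bit_length()
    num = np.zeros(L + 1)
    for n in range(N):
        a = u[:, n, :].copy()
        if member is not None:
            a = a * member[:, n, None]
        fa = np.fft.rfft(a, n=n_fft, axis=0)
        fb = np.fft.rfft(u[:, n, :], n=n_fft, axis=0)
        corr = np.fft.irfft(np.conj(fa) * fb, n=n_fft, axis=0)[: L + 1].sum(axis=1)
        num += corr
    if member is None:
        cnt = (F - np.arange(L + 1)) * N
    else:
        # surviving origin count per lag: Σ_n Σ_{t0 <= F-1-lag} m[t0, n]
        csum = np.cumsum(member.sum(axis=1))
        cnt = csum[F - 1 - np.arange(L + 1)]
    return num, np.asarray(cnt, dtype=np.int64)


@dataclass
class RelaxationTime:
    """τ_R = ∫ C(t) dt split into the numeric and extrapolated-tail parts."""

    tau_R: float  # ps
    tau_numeric: float  # trapezoid up to the last reliable lag
    tau_tail: float  # exponential-tail extrapolation beyond the series
    tail_time_constant: float  # ps; nan when no tail fit was possible
    t_end: float  # ps, integration upper limit
    tau_single_exp: float  # alternative: single-exponential-fit time constant


@dataclass
class RotationalResult:
    series: CorrelationSeries
    relaxation: RelaxationTime
    label: str = ""

    @property
    def tau_R(self) -> float:
        return self.relaxation.tau_R


def relaxation_time(series: CorrelationSeries, *, divergence_level: float = 0.5) -> RelaxationTime:
    """Integrated relaxation time of a decaying orientational correlation.

    Trapezoidal integration over the full series plus an exponential tail
    fitted on the final decade of lags (ln C vs t).  Raises
    :class:`DivergenceError` when the series ends above ``divergence_level``,
    i.e. has not decayed enough for the integral to be meaningful.
    """
    t, c = series.lags, series.values
    ok = np.isfinite(c)
    t, c = t[ok], c[ok]
    if len(t) < 3:
        raise ValueError("series too short for integration")
    if c[-1] > divergence_level:
        raise DivergenceError(
            f"correlation still at {c[-1]:.3f} at the last lag ({t[-1]:g} ps); "
            "τ_R integral diverges — extend the trajectory or fit a model"
        )
    tau_numeric = float(np.trapezoid(c, t))
    # exponential tail from the final decade of lag times
    tail_sel = (t >= t[-1] / 10.0) & (c > 0)
    tau_tail = 0.0
    tail_tc = float("nan")
    if tail_sel.sum() >= 3:
        slope, intercept = np.polyfit(t[tail_sel], np.log(c[tail_sel]), 1)
        if slope < 0:
            tail_tc = -1.0 / slope
            c_end = float(np.exp(intercept + slope * t[-1]))
            tau_tail = c_end * tail_tc
    # alternative convention: single-exponential fit over the decaying part
    pos = c > max(1e-3, 0.0)
    tau_single = float("nan")
    if pos.sum() >= 3:
        s, _ = np.polyfit(t[pos], np.log(c[pos]), 1)
        if s < 0:
            tau_single = -1.0 / s
    return RelaxationTime(
        tau_R=tau_numeric + tau_tail,
        tau_numeric=tau_numeric,
        tau_tail=tau_tail,
        tail_time_constant=tail_tc,
        t_end=float(t[-1]),
        tau_single_exp=tau_single,
    )


def layer_relaxation(
    dipoles: np.ndarray,
    times: np.ndarray,
    assignment: LayerAssignment,
    layer,
    **acf_kwargs,
) -> RotationalResult:
    """Dipole ACF and τ_R for waters resident in ``layer`` at the origin."""
    member = assignment.in_layer(layer)
    series = dipole_acf(dipoles, times, member=member, label=str(layer), **acf_kwargs)
    return RotationalResult(series=series, relaxation=relaxation_time(series), label=str(layer))


def site_selection_mask(
    trajectory: Trajectory, group: str, cutoff: float, *, topology: Topology | None = None
) -> np.ndarray:
    """(n_frames, n_waters) True where the water O is within ``cutoff`` Å of
    any atom of the named solute group (minimum-image distances)."""
    top = topology or trajectory.topology
    if top is None or group not in top.groups:
        raise KeyError(f"named group {group!r} not found in topology")
    if trajectory.box is None:
        raise ValueError("site selection requires a periodic box")
    g_idx = top.groups[group]
    o_idx = top.water_oxygen_indices
    F = trajectory.n_frames
    out = np.empty((F, len(o_idx)), dtype=bool)
    for f in range(F):
        d = trajectory.coords[f, o_idx][:, None, :] - trajectory.coords[f, g_idx][None, :, :]
        d = trajectory.box.min_image(d)
        out[f] = (np.sum(d * d, axis=-1).min(axis=1)) < cutoff**2
    return out


def site_resolved_tau(
    trajectory: Trajectory,
    group: str,
    cutoff: float,
    *,
    dipoles: np.ndarray | None = None,
    **acf_kwargs,
) -> RotationalResult:
    """Rotational relaxation of waters hydrating a named solute site.

    Selection is origin-resident: a water contributes from every origin at
    which its oxygen lies within ``cutoff`` of any group atom.
    """
    member = site_selection_mask(trajectory, group, cutoff)
    if not member.any():
        raise ValueError(f"group {group!r} is never hydrated within {cutoff} Å")
    if dipoles is None:
        dipoles = compute_dipoles(trajectory)
    series = dipole_acf(dipoles, trajectory.times, member=member,
                        label=f"{group}<{cutoff:g}A", **acf_kwargs)
    return RotationalResult(series=series, relaxation=relaxation_time(series),
                            label=f"{group}<{cutoff:g}A")
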