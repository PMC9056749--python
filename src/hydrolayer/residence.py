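"""Residence statistics of water in an interfacial region.

C_R(t) is the probability that a molecule present in the region at an origin
is still there a lag t later, where continuous absences shorter than a
tolerance t* are forgiven (temporary excursions across the region border).
t* = 0 reduces to strict continuous survival; t* → ∞ to the intermittent
two-point correlation.  A double-exponential fit of C_R(t) yields the slow
residence time and a fast border-escape time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlate import CorrelationSeries, DoubleExpFit, fit_double_exponential
from .shells import LayerAssignment

__all__ = ["ResidenceResult", "residence_correlation", "fit_residence_times",
           "tstar_sweep", "layer_region_mask"]


@dataclass
class ResidenceResult:
    """C_R(t) with its double-exponential decomposition."""

    series: CorrelationSeries
    tstar: float  # ps
    fit: DoubleExpFit

    @property
    def residence_time(self) -> float:
        """Slow time constant: the residence time in the region (ps)."""
        return self.fit.tau_slow

    @property
    def escape_time(self) -> float:
        """Fast time constant: escape of border molecules (ps)."""
        return self.fit.tau_fast


def layer_region_mask(assignment: LayerAssignment, layer) -> np.ndarray:
    """Region membership series (n_frames, n_waters) for a layer or union."""
    return assignment.in_layer(layer)


def _absence_run_lengths(member: np.ndarray) -> np.ndarray:
    """Per (frame, molecule): length in frames of the absence run containing
    that frame, 0 where the molecule is present."""
    F, N = member.shape
    out = np.zeros((F, N), dtype=np.int64)
    for n in range(N):
        absent = ~member[:, n]
        if not absent.any():
            continue
        # run-length encode the absence indicator
        edges = np.flatnonzero(np.diff(absent.astype(np.int8)) != 0) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [F]])
        for s, e in zip(starts, ends):
            if absent[s]:
                out[s:e, n] = e - s
    return out


def residence_correlation(
    member: np.ndarray,
    dt: float,
    tstar: float = 2.0,
    *,
    origin_stride: int = 1,
    max_lag: int | None = None,
    common_origins: bool = False,
    label: str = "",
) -> CorrelationSeries:
    """Residence correlation C_R(t) with intermittency tolerance t*.

    A molecule survives from t0 to t0+t iff it is in the region at both
    endpoints and every continuous absence strictly inside the window is
    shorter than ``tstar`` ps (strict inequality).  Origins condition on
    presence, so C_R(0) = 1; origins whose window would extend past the last
    frame are discarded (censored absences are never guessed).

    ``common_origins=True`` restricts every lag to the origin set of the
    largest lag, making C_R exactly non-increasing in t at the cost of
    statistics.
    """
    member = np.asarray(member, bool)
    F, N = member.shape
    if tstar < 0:
        raise ValueError("tstar must be >= 0")
    L = F - 1 if max_lag is None else min(max_lag, F - 1)
    runs = _absence_run_lengths(member)
    # an absence frame is disqualifying when its run lasts >= t* (strict tolerance)
    bad = (~member) & (runs * dt >= tstar)
    cum_bad = np.cumsum(bad, axis=0)
    num = np.zeros(L + 1)
    den = np.zeros(L + 1)
    t0_max_common = F - 1 - L
    for lag in range(L + 1):
        hi = t0_max_common if common_origins else F - 1 - lag
        t0 = np.arange(0, hi + 1, origin_stride)
        if t0.size == 0:
            num[lag] = np.nan
            den[lag] = 0
            continue
        present = member[t0]
        survive = present & member[t0 + lag]
        if lag >= 2:
            interior_bad = cum_bad[t0 + lag - 1] - cum_bad[t0]
            survive = survive & (interior_bad == 0)
        num[lag] = survive.sum()
        den[lag] = present.sum()
    if den[0] == 0:
        raise ValueError("region empty at every origin")
    values = np.divide(num, den, out=np.full(L + 1, np.nan), where=den > 0)
    return CorrelationSeries(lags=np.arange(L + 1) * dt, values=values,
                             counts=den.astype(np.int64), label=label)


def fit_residence_times(
    series: CorrelationSeries,
    *,
    tstar: float = 2.0,
    window: tuple[float, float] | None = None,
) -> ResidenceResult:
    """Double-exponential decomposition of C_R(t).

    The slow constant is the residence time; the fast one the border-escape
    time.  Single-exponential decays come back flagged degenerate with both
    constants equal to the one physical time.
    """
    fit = fit_double_exponential(series, window)
    if fit.degenerate and fit.degenerate_reason == "amplitude at the single-exponential edge":
        # the physically meaningful constant is the one carrying the weight
        tau = fit.tau_slow if fit.amplitude_fast < 0.5 else fit.tau_fast
        fit.tau_fast = fit.tau_slow = tau
    return ResidenceResult(series=series, tstar=tstar, fit=fit)


def tstar_sweep(
    member: np.ndarray,
    dt: float,
    tstars,
    **kwargs,
) -> pd.DataFrame:
    """C_R(t) on a grid of t* values, as a tidy long table.

    Columns: tstar, lag_ps, C_R, count.  Useful because residence times
    become unstable for large tolerances; the sweep makes that visible.
    """
    frames = []
    for ts in tstars:
        series = residence_correlation(member, dt, float(ts), **kwargs)
        frames.append(pd.DataFrame({
            "tstar": float(ts),
            "lag_ps": series.lags,
            "C_R": series.values,
            "count": series.counts,
        }))
    return pd.concat(frames, ignore_index=True)
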