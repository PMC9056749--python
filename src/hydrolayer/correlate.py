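"""Shared correlation-series container and exponential-decay fitting.

The double-exponential fitter here is used both for hydrogen-bond lifetime
correlations and for residence-time correlations, which the analysis treats
as A·exp(−t/τ_fast) + (1−A)·exp(−t/τ_slow) decays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["CorrelationSeries", "DoubleExpFit", "FitError", "fit_double_exponential"]


class FitError(RuntimeError):
    """Raised when a fit fails to converge from every starting point."""


@dataclass
class CorrelationSeries:
    """A correlation function on a lag grid with per-lag sample counts."""

    lags: np.ndarray  # ps
    values: np.ndarray
    counts: np.ndarray  # number of (origin, molecule/pair) samples per lag
    label: str = ""

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts)
        if not (len(self.lags) == len(self.values) == len(self.counts)):
            raise ValueError("lags, values and counts must have equal length")


def _double_exp(t, a, tau_fast, tau_slow):
    return a * np.exp(-t / tau_fast) + (1.0 - a) * np.exp(-t / tau_slow)


@dataclass
class DoubleExpFit:
    """Result of a two-exponential decay fit (fast ≤ slow by convention)."""

    amplitude_fast: float
    tau_fast: float  # ps
    tau_slow: float  # ps
    window: tuple[float, float]
    residual: float  # RMS residual over the fit window
    degenerate: bool = False
    degenerate_reason: str = ""
    n_points: int = 0
    starts_tried: int = 0

    @property
    def amplitude_slow(self) -> float:
        return 1.0 - self.amplitude_fast

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return _double_exp(np.asarray(t, float), self.amplitude_fast, self.tau_fast, self.tau_slow)


def fit_double_exponential(
    series: CorrelationSeries,
    window: tuple[float, float] | None = None,
    *,
    n_starts: int = 8,
    degeneracy_rtol: float = 0.05,
    amplitude_edge: float = 0.02,
) -> DoubleExpFit:
    """Least-squares fit of A·exp(−t/τ₁) + (1−A)·exp(−t/τ₂) to a decay.

    Runs ``n_starts`` initialisations with trial time constants spanning two
    decades around the series' own decay scale, keeps the lowest-residual
    converged fit, and orders the constants fast ≤ slow.  A fit collapsing to
    a single exponential (equal constants within ``degeneracy_rtol`` or an
    amplitude at the 0/1 edge) is returned with ``degenerate=True`` rather
    than rejected: single-exponential decays are legitimate inputs.
    """
    t = series.lags
    y = series.values
    if window is not None:
        lo, hi = window
        sel = (t >= lo) & (t <= hi)
    else:
        sel = np.ones(len(t), dtype=bool)
    sel &= np.isfinite(y)
    t_fit, y_fit = t[sel], y[sel]
    if len(t_fit) < 4:
        raise FitError(f"only {len(t_fit)} points in fit window; need >= 4")
    if np.all(y_fit <= 0):
        raise FitError("series non-positive over the fit window")

    # crude decay scale from the lag where the series first falls below 1/e
    y0 = y_fit[np.argmin(t_fit)] if t_fit.min() > 0 else y_fit[t_fit == t_fit.min()][0]
    below = t_fit[y_fit < y0 / np.e]
    scale = float(below.min()) if below.size else float(t_fit.max() / 2)
    scale = max(scale, float(np.diff(np.sort(t_fit)).min()) if len(t_fit) > 1 else 1.0)

    rng = np.random.default_rng(0)  # deterministic jitter of start points
    trial_fast = scale * np.logspace(-1.0, 0.5, n_starts)
    trial_slow = scale * np.logspace(0.0, 1.0, n_starts)
    best: DoubleExpFit | None = None
    tried = 0
    for tf, ts in zip(trial_fast, trial_slow):
        for a0 in (0.3, 0.7):
            tried += 1
            p0 = (a0, tf * (1 + 0.01 * rng.standard_normal()), ts)
            try:
                popt, _ = curve_fit(
                    _double_exp,
                    t_fit,
                    y_fit,
                    p0=p0,
                    bounds=([0.0, 1e-12, 1e-12], [1.0, np.inf, np.inf]),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError):
                continue
            a, tau1, tau2 = popt
            if tau1 > tau2:
                tau1, tau2, a = tau2, tau1, 1.0 - a
            resid = float(np.sqrt(np.mean((_double_exp(t_fit, a, tau1, tau2) - y_fit) ** 2)))
            if best is None or resid < best.residual:
                best = DoubleExpFit(
                    amplitude_fast=float(a),
                    tau_fast=float(tau1),
                    tau_slow=float(tau2),
                    window=(float(t_fit.min()), float(t_fit.max())),
                    residual=resid,
                    n_points=len(t_fit),
                    starts_tried=tried,
                )
    if best is None:
        raise FitError(
            f"double-exponential fit failed to converge from {tried} starts "
            f"(window {t_fit.min():g}-{t_fit.max():g} ps, {len(t_fit)} points)"
        )
    # model comparison: when one exponential explains the data essentially as
    # well, the two-constant split is ill-conditioned and its constants biased
    single = _fit_single_exp(t_fit, y_fit)
    if single is not None:
        tau_s, resid_s = single
        if resid_s <= best.residual * 1.02 + 1e-12:
            best.tau_fast = best.tau_slow = tau_s
            best.amplitude_fast = 1.0
            best.residual = resid_s
            best.degenerate = True
            best.degenerate_reason = "single exponential fits equally well"
            return best
    if best.tau_slow > 0 and (best.tau_slow - best.tau_fast) / best.tau_slow < degeneracy_rtol:
        best.degenerate = True
        best.degenerate_reason = "time constants indistinguishable"
    elif best.amplitude_fast < amplitude_edge or best.amplitude_fast > 1 - amplitude_edge:
        best.degenerate = True
        best.degenerate_reason = "amplitude at the single-exponential edge"
    return best


def _fit_single_exp(t: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Best a·exp(−t/τ) fit; returns (τ, RMS residual) or None on failure."""
    pos = y > 0
    if pos.sum() < 3:
        return None
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    if slope >= 0:
        return None
    p0 = (min(float(np.exp(intercept)), 1.0), -1.0 / slope)
    try:
        popt, _ = curve_fit(lambda tt, a, tau: a * np.exp(-tt / tau), t, y,
                            p0=p0, bounds=([0.0, 1e-12], [1.5, np.inf]), maxfev=20000)
    except (RuntimeError, ValueError):
        return None
    a, tau = popt
    resid = float(np.sqrt(np.mean((a * np.exp(-t / tau) - y) ** 2)))
    return float(tau), resid
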