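#!/usr/bin/env python
"""Residence kinetics and two-exponential lifetime decompositions.

The shell-exchange ensemble (escape rate k = 0.05 /ps, no re-entry) has the
closed-form survival C_R(t) = exp(−k·t): at t* = 0 the fitted slow time must
recover 1/k = 20 ps.  A t* sweep shows how the intermittency tolerance
forgives brief excursions.  Finally the two-exponential fitter is profiled on
constructed bond-lifetime decays (2.7/13.3 ps bulk-like scale and 2/13.1 ps
residence-like scale).  Writes results/residence/*.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hydrolayer.correlate import CorrelationSeries, fit_double_exponential
from hydrolayer.residence import fit_residence_times, residence_correlation, tstar_sweep
from hydrolayer.synthetic_data import SyntheticSpec, gen_shell_exchange

OUT = Path("results/residence")
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SyntheticSpec(kind="shell_exchange", n_particles=1500, n_frames=1200,
                         dt=0.1, box_length=40.0, seed=SEED + 4,
                         params={"k_out": 0.05, "k_in": 0.0, "radius": 4.0})
    states = gen_shell_exchange(spec).ground_truth["states"]
    series = residence_correlation(states, spec.dt, 0.0, max_lag=600, origin_stride=3)
    fit = fit_residence_times(series, tstar=0.0)
    pd.DataFrame({"lag_ps": series.lags, "C_R": series.values}) \
        .to_csv(OUT / "cr_exchange.csv", index=False)
    print(f"exchange fixture: residence time {fit.residence_time:.2f} ps "
          f"(closed form 20.0), degenerate single-exponential: {fit.fit.degenerate}")

    sweep = tstar_sweep(states[:, :400], spec.dt, [0.0, 1.0, 2.0, 4.0],
                        max_lag=300, origin_stride=3)
    sweep.to_csv(OUT / "tstar_sweep.csv", index=False)
    at = sweep[sweep["lag_ps"] == 20.0].set_index("tstar")["C_R"]
    print("C_R(20 ps) vs t*: " + ", ".join(f"t*={k:g}: {v:.3f}" for k, v in at.items())
          + "  (non-decreasing in t*)")

    t = np.arange(0, 80, 0.2)
    rows = []
    for a, t1, t2 in [(0.5, 2.7, 13.3), (0.3, 2.0, 13.1)]:
        y = a * np.exp(-t / t1) + (1 - a) * np.exp(-t / t2)
        f = fit_double_exponential(CorrelationSeries(t, y, np.ones_like(t)))
        rows.append((t1, t2, f.tau_fast, f.tau_slow, f.residual))
    df = pd.DataFrame(rows, columns=["tau_fast_true", "tau_slow_true",
                                     "tau_fast_fit", "tau_slow_fit", "residual"])
    df.to_csv(OUT / "double_exp_recovery.csv", index=False)
    print(df.to_string(index=False))
    print(f"\ntables under {OUT}/")


if __name__ == "__main__":
    main()
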