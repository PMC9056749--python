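#!/usr/bin/env python
"""Rotational dynamics: dipole autocorrelation and relaxation time.

A rotor ensemble with rotational diffusion constant D_r = 0.025 /ps has the
closed-form first-rank correlation C(t) = exp(−2·D_r·t) and integrated
relaxation time τ_R = 1/(2·D_r) = 20 ps.  The script measures both, plus the
two-population (slow/fast) site-selection variant that mimics waters anchored
at strongly hydrated solute sites.  Writes results/rotational/*.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hydrolayer.rotational import dipole_acf, relaxation_time
from hydrolayer.synthetic_data import SyntheticSpec, gen_rotor

OUT = Path("results/rotational")
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    d_r = 0.025
    spec = SyntheticSpec(kind="rotor", n_particles=500, n_frames=5000, dt=0.1,
                         box_length=10.0, seed=SEED + 5, params={"D_r": d_r})
    res = gen_rotor(spec)
    series = dipole_acf(res.dipoles, spec.times, max_lag=2500)
    rt = relaxation_time(series)
    pd.DataFrame({"lag_ps": series.lags, "C": series.values,
                  "C_closed_form": np.exp(-2 * d_r * series.lags)}) \
        .to_csv(OUT / "dipole_acf.csv", index=False)
    print(f"rotor: tau_R = {rt.tau_R:.2f} ps (closed form {1 / (2 * d_r):.1f} ps; "
          f"numeric {rt.tau_numeric:.2f} + tail {rt.tau_tail:.2f})")

    # slow population near an anchoring site vs fast population elsewhere
    slow = gen_rotor(SyntheticSpec(kind="rotor", n_particles=250, n_frames=4000,
                                   dt=0.1, box_length=10.0, seed=SEED + 6,
                                   params={"D_r": 0.025}))
    fast = gen_rotor(SyntheticSpec(kind="rotor", n_particles=250, n_frames=4000,
                                   dt=0.1, box_length=10.0, seed=SEED + 7,
                                   params={"D_r": 0.25}))
    u = np.concatenate([slow.dipoles, fast.dipoles], axis=1)
    member = np.zeros(u.shape[:2], dtype=bool)
    member[:, :250] = True
    t = slow.spec.times
    rows = []
    for label, m in [("site(slow)", member), ("elsewhere(fast)", ~member), ("all", None)]:
        s = dipole_acf(u, t, member=m, max_lag=2000)
        rows.append((label, relaxation_time(s).tau_R))
    df = pd.DataFrame(rows, columns=["selection", "tau_R_ps"])
    df.to_csv(OUT / "site_resolved_tau.csv", index=False)
    print(df.to_string(index=False))
    print(f"\ntables under {OUT}/")


if __name__ == "__main__":
    main()
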