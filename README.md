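# hydrolayer

Layer-resolved dynamics of interfacial water around a solute, for molecular
simulation data. Given an MD trajectory (XYZ or DL_POLY HISTORY) and a
topology separating solute from water, `hydrolayer` decomposes the solvent
into distance shells (0–4, 4–8, 8–12, 12–16 Å, then bulk) and computes, per
shell:

- **hydrogen bonding** — geometric criteria (H···O < 2.5 Å, O···O < 3.5 Å,
  optional 30° angle), mean n_HB per water, water–solute bond counts, the
  intermittent bond-population correlation C_HB(t) with two-exponential
  lifetimes, and a 3-D hydration density map;
- **translational dynamics** — origin-averaged MSD under a continuous-
  residence membership rule, the generalized Einstein fit MSD(t) = D·t^α
  (α = 1 diffusive, α < 1 sub-diffusive, α > 1 super-diffusive, α = 2
  ballistic), self-diffusion via MSD = 6·D_S·t, and the self van Hove
  function G_s(r, t) whose secondary maxima expose translational hopping;
- **rotational dynamics** — the dipole autocorrelation
  C(t) = ⟨u(t0)·u(t0+t)⟩ and its integrated relaxation time
  τ_R = ∫C(t)dt, also resolved around named solute sites;
- **residence kinetics** — the survival correlation C_R(t) with an
  intermittency tolerance t* (absences shorter than t* forgiven) and its
  two-exponential residence/escape decomposition;
- **solute shape** — gyration tensor, R_g, asphericity, and superposed RMSD.

Because real interfacial-water MD is expensive and rarely redistributable,
the package ships a first-class synthetic-trajectory generator with known
ground truth (Brownian, ballistic, rest-and-jump/Lévy hopping, rotational
diffusion, a hydrogen-bond-saturated tetrahedral lattice, two-state shell
exchange, and a composite system), so every estimator is validated by
recovery of the parameters that built the data. See `docs/methods.md` for
models, conventions and limitations.

## Worked example

```python
import numpy as np
from hydrolayer import SyntheticSpec, generate, unwrap, msd_layered, fit_power_law
from hydrolayer.translational import classify_regime, van_hove_self, find_secondary_modes

# Brownian ensemble with known D = 0.2 Å²/ps
spec = SyntheticSpec(kind="brownian", n_particles=200, n_frames=2000,
                     dt=0.1, box_length=50.0, seed=2026, params={"D": 0.2})
traj = unwrap(generate(spec).trajectory)
fit = fit_power_law(msd_layered(traj), (0.1, 20.0))
print(f"alpha = {fit.alpha:.4f}  D_S = {fit.D_self:.4f} A^2/ps "
      f"({classify_regime(fit.alpha).label})")

# rest-and-jump ensemble: 8 Å hops every ~10 ps
hop = SyntheticSpec(kind="levy_hop", n_particles=300, n_frames=250, dt=0.1,
                    box_length=40.0, seed=2027,
                    params={"hop_length": 8.0, "tau_wait": 10.0})
pos = generate(hop).ground_truth["unwrapped"]
vh = van_hove_self(pos, [10.0], bins=np.linspace(0, 40, 161), times=hop.times)
print("secondary van Hove modes at 10 ps:", np.round(find_secondary_modes(vh, 10.0), 2))
```

prints

```
alpha = 1.0043  D_S = 0.1999 A^2/ps (diffusive)
secondary van Hove modes at 10 ps: [8.12]
```

— the fitted exponent is diffusive within fit noise, the recovered
diffusivity matches the generator's 0.2 Å²/ps, and the hop length appears
as a distinct displacement mode near 8 Å (the hopping signature; a Brownian
control shows no such mode).

The numbered drivers under `analysis/` run the full study on the synthetic
systems — `01_generate_synthetic.py` through `06_full_pipeline.py` — each
printing what it found and writing tidy tables under `results/`. The same
pipeline runs from a shell:

```bash
hydrolayer generate --kind composite --output results/synthetic --n-particles 60
hydrolayer analyze --config config.yaml
hydrolayer validate --seed 0
```

`validate` reruns the ground-truth recoveries (ballistic α = 2, Brownian
α = 1 and D_S, rotor τ_R = 1/(2 D_r), exchange residence time = 1/k,
lattice n_HB = 4) and reports expected vs. recovered values.

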