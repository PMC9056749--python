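# Methods

`hydrolayer` quantifies the dynamics of water near a solute, resolved by
hydration layer. This note records the models implemented, the conventions
and numerical choices adopted where several were defensible, what the
synthetic generators do and do not emulate, and the known limitations.

## Units and containers

Coordinates are in Å, times in ps, masses in amu, charges in e throughout.
A `Trajectory` stores wrapped coordinates `(n_frames, n_atoms, 3)` with a
constant orthorhombic box and a constant `Topology` (per-atom element, mass,
charge, molecule id and role: solute / water-O / water-H / ion, plus named
solute groups for site-resolved selections). Frame times must be strictly
increasing with a uniform step; the frame interval is whatever the input
declares — the pipeline accepts any uniform interval and records it in the
run log. Triclinic cells are rejected: every distance criterion in the
analysis uses the orthorhombic minimum-image convention, and supporting
skewed cells would complicate all of them for no present need.

Unwrapping reconstructs continuous coordinates by accumulating minimum-image
inter-frame displacements. This is exact only if no atom moves ≥ L/2
between frames; a violation is detected (a minimum-image displacement at the
L/2 boundary) and raised as an undersampling error naming atom and frame,
because silently unwrapping such data corrupts every displacement statistic
downstream.

## Hydration layers

Each water is assigned per frame to a distance layer by the minimum
minimum-image distance from its oxygen (default; centre of mass optional) to
any solute atom. Default edges are 0–4–8–12–16 Å — 4 Å is a typical first
hydration-shell radius from solute–water radial distribution functions —
with everything beyond the last edge labelled bulk. Bins are half-open
[e_k, e_k+1): boundary handling is a pure convention and this one makes the
layers an exact partition. For layer-restricted displacement statistics the
default membership rule is continuous residence over the whole (t0, t0+t)
window; an endpoints-only rule is available as a flag, since the looser
reading ("present at both origin times") is also defensible for exchange-
dominated shells. The rule in force is recorded in the run log.

## Hydrogen bonds

A hydrogen bond exists between a donor H (with its parent heavy atom) and an
acceptor heavy atom when H···O < 2.5 Å and O···O < 3.5 Å, strict
inequalities. The optional angle criterion (O–H/O–O angle < 30°) is off by
default: under the two distance criteria near-linear geometries already
dominate, and enabling it can only remove bonds (asserted as a property
test). Water–water and water–solute bonds are both reported, tagged `ww` /
`ws`; solute O and N atoms act as acceptors, and solute hydrogens bonded to
a polar parent act as donors. n_HB per water counts a `ww` bond once for the
donor and once for the acceptor molecule, attributed to the layer the water
occupies that frame; the per-layer spread is the frame-to-frame standard
deviation of the layer mean. The water–solute count is reported under both
normalisations (per interfacial water and per solute polar site), because
either is a defensible definition of a surface-hydration count.

The bond-population correlation C_HB(t) is intermittent: it conditions on a
(unordered) molecule pair being bonded at the origin and asks whether it is
bonded at lag t, regardless of intermediate breaks. C_HB(0) = 1 by
construction. Layer restriction keeps pairs with at least one member
resident at the origin.

## Translational dynamics

The layer-restricted MSD averages |r_com(t0+t) − r_com(t0)|² over all time
origins (configurable stride) and over the molecules passing the membership
rule; displacements use the mass-weighted centre of mass while layer
membership uses the oxygen, and both choices are recorded. Lags with no
surviving molecule are flagged missing (NaN), never zero. The unrestricted
path uses the FFT autocorrelation identity (O(N F log F)) and is tested to
agree with the O(F²) double loop to floating precision; the restricted path
evaluates per-lag with a precomputed residence-streak table.

The generalized Einstein relation MSD = D·t^α is fitted by unweighted least
squares of log MSD on log t (t = 0 excluded); the named windows `alpha1`
(0–0.3 ns) and `alpha2` (0.5–3 ns) bracket the interfacial time crossover
and are fixed windows, not auto-detected. Regime classification calls
|α−1| ≤ 0.05 diffusive; the "ballistic" label is reserved for exponents
equal to 2 at fit precision (10⁻³), while a super-diffusive exponent within
0.05 of 2 carries a near-ballistic note — a measured 1.99 on noisy data is
super-diffusion, not ballistic motion.

The self van Hove function is computed as the distance distribution of
displacement magnitudes per lag, normalised so the radial integral is 1
(within 10⁻⁶, asserted). Secondary maxima — the hopping signature — are
detected with a prominence threshold of 5% of the main-mode height; the
main mode is taken as the global maximum bin because for rest-and-jump
motion it sits at r ≈ 0, on the histogram boundary where a peak finder
cannot flag it.

## Rotational dynamics

The water dipole is the charge-weighted geometry vector (hydrogens unfolded
to their oxygen first), normalised to a unit vector. C(t) is the first-rank
(P₁) autocorrelation ⟨u(t0)·u(t0+t)⟩ — the literal reading of a dipole
vector correlation; P₂ is available behind a flag. Selection is resident-at-
origin only (not continuous residence): relaxation times of tens of ps would
otherwise be truncated by fast exchange out of a 4 Å shell. τ_R is the time
integral of C(t): trapezoid over the available lags plus an exponential tail
fitted on the final decade of lag times, with the tail contribution reported
separately; a series still above 0.5 at its last lag raises a divergence
error instead of returning a truncated integral. A single-exponential-fit
τ is also reported for comparison, since the integral and the fit differ for
non-exponential decays.

## Residence kinetics

C_R(t) is the probability that a molecule in the region at an origin is
there again at t0+t with every continuous absence inside the window strictly
shorter than t* (default 2 ps). Absences are measured in ps (frames × dt).
t* = 0 reduces exactly to continuous survival, t* → ∞ to the intermittent
two-point correlation — both asserted as properties. Origins condition on
presence (so C_R(0) = 1), and origins whose window would cross the last
frame are discarded rather than guessing censored absences. One subtlety:
for t* > 0 the estimator is *not* pointwise monotone in t (an excursion that
covers one lag's endpoint is forgiven at a larger lag), so monotonicity in
lag is only asserted for t* = 0; monotonicity in t* holds exactly and is
asserted on every fixture. A built-in t* sweep exports C_R on a grid of
tolerances, because residence times become unstable for large t*.

## Two-exponential fits

Both HB lifetimes and residence times use one fitter:
A·exp(−t/τ_fast) + (1−A)·exp(−t/τ_slow), A ∈ [0, 1], non-linear least
squares from 16 deterministic multi-starts spanning two decades of time
constants around the series' own 1/e scale, lowest residual wins, constants
ordered fast ≤ slow. A fit is flagged degenerate when a single exponential
explains the data essentially as well (within 2% RMS residual — in that
case the two-constant split is ill-conditioned and its constants biased, so
the single-exponential τ is returned for both), when the constants are
within 5% of each other, or when the amplitude sits at the 0/1 edge.
Degenerate inputs are legitimate (a memoryless exchange process *is* a
single exponential), hence a flag rather than an error.

## Solute shape

The gyration tensor is the mass-weighted (default; geometric optional)
second moment about the centroid; eigenvalues are reported descending and
sum to R_g² (asserted to 10⁻¹⁰), the leading eigenvector is the long axis.
Asphericity is b = λ₁ − (λ₂+λ₃)/2, reported raw (Å²) and normalised by
R_g²; the standard gyration-tensor form is adopted since several variants
exist. RMSD to the reference conformation uses optimal superposition by
default (Kabsch via quaternions, proper rotations only — reflections are
excluded), with a raw centroids-aligned option; superposition is the
conservative choice when the provenance of a quoted RMSD is unknown, and
superposed RMSD ≤ raw RMSD always.

The hydration density map superposes every frame's solute onto the
reference conformation, carries the water oxygens through the same rigid
transform, and bins those within the cutoff (default 4 Å) of any solute
atom on a grid (default 1 Å). The grid integral equals the mean water
count within the cutoff (asserted), and the map is written as OpenDX text
for molecular viewers.

## Synthetic generators

Each generator produces one statistical structure with known ground truth:

- **brownian** — independent Gaussian increments, per-axis variance 2·D·dt
  (default D = 0.2 Å²/ps, a liquid-water-like diffusivity); MSD = 6·D·t.
- **ballistic** — r(t) = r0 + v·t, isotropic directions, speeds uniform in
  [0.5, 1.5]× the nominal speed (1 Å/ps); MSD = ⟨v²⟩t².
- **levy_hop** — rest at a site for Exp(τ_w = 10 ps), then an instantaneous
  jump of fixed length ℓ = 8 Å (truncated-Pareto option) in a random
  direction; the fixed length puts the van Hove secondary mode exactly at ℓ.
  Hop events are logged. Jumps ≥ L/2 are rejected (they would break
  unwrapping).
- **rotor** — tangent-plane Euler steps on the unit sphere with
  ⟨u(0)·u(t)⟩ = exp(−2 D_r t); default D_r = 0.025 /ps gives τ_R = 20 ps,
  the scale of interfacial water anchored at polar sites.
- **hb_lattice** — diamond-cubic oxygens at O–O = 2.8 Å with a uniformly
  polarised ice-rules hydrogen assignment (every molecule donates 2, accepts
  2, H on the donor O–O axis at 1.0 Å); under periodic boundaries every
  molecule has exactly 4 bonds under the geometric criteria, and a
  non-periodic variant exposes undercoordinated surface molecules.
- **shell_exchange** — a two-state telegraph process (escape rate k_out,
  re-entry rate k_in) around a dummy solute, positions placed consistently
  with the state, optional injected sub-t* excursions; the exact state
  series is the ground truth.
- **composite** — rigid three-site waters (O–H 0.9572 Å, H–O–H 104.52°, so
  dipoles are well defined) whose oxygens follow Brownian paths and whose
  axes follow rotational diffusion, around a small rigid solute cluster;
  the end-to-end pipeline fixture.

All randomness flows from per-particle `SeedSequence` streams spawned from
the spec seed, so a trajectory is reproducible from (spec, seed) alone and
extending `n_frames` does not change earlier increments. Ground truth is
consumed only by recovery tests, never by the analysis path.

What the generators deliberately do **not** emulate: physical forces,
hydrogen-bond networks with realistic geometry and kinetics coupled to
translation, solvent structure (g(r)), thermostats, or any force-field
thermodynamics. Passing recovery tests therefore demonstrates that the
estimators measure what they claim on processes with those statistics — not
that a particular simulation of a particular peptide is correct.

## Problem sizes

Recovery runs use ensembles chosen so statistical error sits comfortably
inside the stated tolerances: 100 ballistic × 1000 frames, 200 Brownian ×
2000 frames (dt = 0.1 ps), 500 rotors × 5000 frames, 1500 exchange
particles × 1200 frames, a 2³-cell (64-water) lattice. At these sizes every
recovery is a matter of seconds on one core, and estimator error is
dominated by Monte-Carlo noise of known magnitude rather than by fit bias.

## Known limitations

- Orthorhombic boxes only; no DCD/XTC readers (XYZ, DL_POLY HISTORY, PDB
  topology bootstrap).
- The intermittent C_HB pair matrix is dense over all pairs ever bonded;
  for very long, very dense trajectories this is memory-hungry.
- The density map assumes a rigid enough solute that superposition onto one
  reference conformation is meaningful.
- Residence and C_HB estimators loop per lag; use `origin_stride`/`max_lag`
  for long trajectories.
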