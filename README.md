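# namdnn

Neural network potentials for **multiple electronic states** and
**surface-hopping nonadiabatic dynamics**, validated end to end on analytic
model Hamiltonians — no external quantum-chemistry data required.

Photochemistry lives on several coupled potential energy surfaces: after
light absorption a molecule relaxes through regions where adiabatic states
approach and cross (conical intersections), and the quantities that govern
those transitions are awkward for machine learning. The nonadiabatic
coupling vector `C_ij = ⟨ψ_i|∂/∂R|ψ_j⟩` diverges at state degeneracies, and
both `C_ij` and the transition dipole `μ_ij` carry an arbitrary sign per
data point (each wavefunction is defined only up to a global phase). This
package implements the full pipeline that deals with both problems:

* **Data model** — per-geometry multi-state records (energies `E_j`, forces
  `F_j`, couplings `C_ij`, dipoles `μ_j`, `μ_ij`) in a portable extended-XYZ
  text format, with unit conversion, splitting and target scaling. Couplings
  are stored and learned in smoothed form `C̃_ij = C_ij · (E_j − E_i)`,
  which stays finite at intersections; classical couplings are recovered at
  prediction time by dividing out the (floored) gap.
* **Representations** — a rotationally invariant continuous-filter
  message-passing network (scalar features) and an equivariant variant
  carrying per-atom vector features, on a small numpy autodiff engine that
  supports gradients of gradients.
* **Property heads** — per-state energies; forces as exact energy
  derivatives; smoothed couplings either directly from vector features
  (equivariant) or as derivatives of a virtual invariant scalar; dipoles
  from a latent atomic-charge model.
* **Phase-free training** — losses minimized over per-pair signs or over
  all `2^(S−1)` consistent per-state phase vectors, so raw sign-scrambled
  reference data train as well as phase-corrected data.
* **Fewest-switches surface hopping** — velocity-Verlet nuclei, unitary
  electronic propagation, stochastic hops with energy-conserving momentum
  rescaling, decoherence damping, total-energy monitoring, ensemble
  populations and sequential-kinetics lifetimes.
* **Spectra** — oscillator strengths `f = (2/3)·ΔE·‖μ_ij‖²` with Gaussian
  broadening (0.1 eV FWHM default) over geometry ensembles.
* **Synthetic models** — analytic diabatic Hamiltonians (1D avoided
  crossing, 2D conical intersection, 3-state extension) providing exact
  energies, forces, couplings and dipoles as training data and as oracles,
  including deliberate sign scrambling and harmonic Wigner sampling.

See `docs/methods.md` for the models, algorithms and numerical choices.

## Worked example

Generate sign-scrambled data from the built-in 2D conical-intersection
model, train an equivariant model on energies, forces, couplings and
dipoles, then run photodynamics and a spectrum:

```bash
namdnn make-synthetic --model ci2d --n 600 --phase-corruption 1.0 \
       --seed 7 --out db.exxyz
namdnn split-db --db db.exxyz --fractions 0.8,0.1,0.1 --seed 0
namdnn train --config run.yaml --train-db db.train.exxyz \
       --val-db db.val.exxyz --seed 0 --out model.npz
namdnn evaluate --model model.npz --db db.test.exxyz
```

with `run.yaml`:

```yaml
representation:
  kind: equivariant
  n_features: 32
  n_interactions: 3
heads:
  dipoles: true
loss:
  phase_mode: phase_vector
training:
  epochs: 25
  lr: 0.01
  batch_size: 120
```

On this deliberately small budget (480 training samples, 25 epochs, under
a minute of CPU) the held-out errors are already

```
property                      MAE         RMSE        n
energies              6.47513e-03  6.98266e-03      120
forces                4.38461e-03  6.72736e-03     1080
smooth_nacs           7.80561e-03  1.21479e-02      540
transition_dipoles    4.99075e-02  7.57053e-02      180
permanent_dipoles     3.63335e-02  4.73297e-02      360
```

(MAE/RMSE in atomic units over all tensor components; couplings and
transition dipoles are scored modulo the best phase vector per sample,
since reference signs are arbitrary). The benchmark configuration in
`namdnn.benchmark` (2000 samples, 60 epochs) reaches a few 1e-4 Ha on
energies and ~1e-3 a.u. on couplings.

Surface-hopping dynamics on the learned surfaces, starting from a Wigner
ensemble vertically excited to S1:

```bash
namdnn dynamics --model model.npz --ntraj 50 --tmax-fs 100 --seed 3 --out dyn
```

`dyn/populations.tsv` records the active-state populations over time with
binomial standard errors and the number of still-valid trajectories (three
of the fifty exceeded the 0.2 eV total-energy-drift bound and are excluded
from later times):

```
time_fs  p0        p1        se0       se1       n_valid
0.000    0.000000  1.000000  0.000000  0.000000  50
...
100.000  0.787234  0.212766  0.059697  0.059697  47
```

`dyn/kinetics.json` holds the sequential-kinetics fit of these populations
(here τ(S1) ≈ 70 fs; the residual 0.097 reports that a single-exponential
chain only roughly describes this small, partly equilibrating ensemble).
The absorption spectrum of the test geometries,

```bash
namdnn spectra --model model.npz --geoms db.test.exxyz --out spec.tsv
```

peaks at 0.51 eV, the vertical S0→S1 gap region of this model's
Franck–Condon ensemble.

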