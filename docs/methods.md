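# Methods

This note documents the models, algorithms and numerical choices behind
`namdnn`: multi-state neural network potentials with phase-free training,
fewest-switches surface hopping (FSSH) driven by those potentials, and the
analytic diabatic model Hamiltonians used to generate data and to serve as
exact oracles.

Internal units are Hartree atomic units throughout (energy in Hartree,
length in Bohr, dipoles in e·Bohr, mass in electron masses, time in
ħ/Hartree); files and external tables declare their units and are converted
on load.

## Multi-state properties and the coupling problem

For S singlet electronic states the package handles, per geometry:
per-state energies `E_j` and forces `F_j = −∂E_j/∂R`; per state pair
(i < j) the nonadiabatic coupling vector (derivative coupling)
`C_ij = ⟨ψ_i|∂/∂R|ψ_j⟩`, its smoothed form `C̃_ij = C_ij · (E_j − E_i)`,
and the transition dipole `μ_ij`; and per-state permanent dipoles `μ_j`.
Two properties of the couplings shape the whole design:

1. **Divergence at degeneracies.** `C_ij` grows like the inverse gap near a
   conical intersection. The smoothed coupling `C̃_ij` stays bounded there,
   so it is the quantity that is stored, learned and predicted; classical
   couplings are recovered at prediction time by dividing by the gap,
   clamped at a floor (`gap_floor`, default 1e-8 Hartree, sign of a zero
   gap taken as +1) so the operation is total.
2. **Arbitrary signs.** Each wavefunction carries an arbitrary global phase
   p_j ∈ {−1, +1}, so every pair property may appear multiplied by p_i·p_j,
   inconsistently across a dataset. Training must therefore be phase-free
   (below), and evaluation scores coupled properties modulo the best phase
   vector per sample.

Pairs are stored with i < j in lexicographic order; `C_ji = −C_ij` is
derived, never stored.

## Representations

Two message-passing atomistic representations share one interface:

* **invariant** — continuous-filter convolutions over interatomic
  distances (SchNet-like): per-atom scalar features, exactly invariant
  under rotations, translations and reflections.
* **equivariant** — scalar plus vector per-atom features (paiNN-like):
  messages carry radial filters times unit displacement vectors, updates
  mix vector channels linearly and gate them with scalars. Vector features
  transform exactly as Cartesian vectors, enabling direct prediction of
  vectorial observables.

Distances enter through 20 Gaussian radial basis functions damped by a
cosine cutoff envelope ½(cos(πr/r_c)+1) that vanishes identically at the
cutoff (default 10 Bohr — effectively global for the small study
molecules). Defaults: 32 feature channels, 3 interaction blocks. Three
blocks follow the usual choice for this architecture family; 32 channels
(rather than the 64+ used for real molecules) keep CPU training of the
synthetic study fast while leaving large accuracy margins on its smooth
low-dimensional surfaces. Both are configurable.

The networks are built on a small reverse-mode autodiff engine
(`namdnn.autodiff`) whose vector-Jacobian products are themselves tape
operations, so gradients of gradients work: forces are exact derivatives
of the predicted energies *and* a force loss can be backpropagated into
the parameters.

## Property heads

* **Energies** — per-state atomwise sums plus per-state reference offsets
  (training-set means). Invariant by construction.
* **Forces** — exact negative gradients of the energy head (never a
  separate head), so energy/force consistency is structural.
* **Smoothed couplings** — two modes:
  * `equivariant_direct`: per-atom gated linear combinations of the vector
    features, one 3-vector per atom per pair (requires the equivariant
    representation);
  * `virtual_derivative`: the gradient of a per-pair invariant scalar
    ("virtual property") — the only option for the invariant
    representation. Note this constrains the predicted coupling field to
    be curl-free, which the true smoothed-coupling field is not; this
    representability gap is one reason the equivariant model reaches a
    lower coupling error on the benchmark.
* **Dipoles** — a latent-charge model: `μ = Σ_a q_a (R_a − R_centroid)`
  with per-state charges shifted uniformly to sum to the total molecular
  charge and per-pair (transition) charges re-centred to zero net charge,
  which makes transition dipoles rigorously translation invariant. The
  geometric centroid as origin keeps permanent dipoles of ions
  well-defined.

Head output layers are zero-initialized, so an untrained model predicts
exactly the reference offsets; this stabilizes the first optimization steps.

## Phase-free losses and training

The combined objective is `L = Σ_P t_P · L_P` over the active properties
(weights `t_P` default to 1). Energies, forces and permanent dipoles use
plain MSE. Coupled properties — smoothed couplings and transition dipoles,
which share one sign per pair — go through a phase-free loss:

* `pairwise`: minimize over an independent ±1 per state pair;
* `phase_vector` (default): minimize over all 2^(S−1) consistent per-state
  sign vectors (p_0 ≡ +1). Always ≥ the pairwise loss and ≤ plain MSE;
  identical to it for S = 2. Enumeration is exponential, so S ≤ 12 is
  enforced and larger state spaces must use `pairwise`.

The minimizing signs are selected per molecule from the current
predictions and held constant during differentiation (the minimum is
piecewise smooth). An `atomistic` flag normalizes per-pair errors by atom
count before reduction. Evaluation (MAE/RMSE tables, error maps) likewise
scores coupled properties modulo the best phase vector per sample.

Optimization is Adam with optional plateau decay; early stopping keeps the
parameters of the best validation epoch and stops after `patience` (default
300) epochs without improvement. Runs are bit-reproducible from (seed,
config, split).

## Synthetic diabatic models

Analytic few-state diabatic Hamiltonians play the role of the quantum
chemistry reference: they give exact adiabatic energies (eigenvalues),
Hellmann–Feynman forces, couplings `C̃_ij = u_iᵀ(∇V)u_j` (so
`C_ij = C̃_ij/(E_j−E_i)` exactly), and eigenvector-transformed dipoles at
any geometry. Eigenvector signs follow a fixed convention
(largest-magnitude component positive, ties to the lowest index); dataset
generation can then deliberately scramble signs: with probability
`phase_corruption`, a random phase vector multiplies a sample's couplings
and transition dipoles jointly — emulating raw quantum-chemistry output.

The models live on real few-atom molecules, with the diabatic matrix a
function of bond-length internal coordinates. This matters: an invariant
network sees only interatomic distances, so a model mapped onto a single
free atom would be unlearnable by construction. The 2D conical-intersection
model (`ci2d`) uses three atoms (masses 4, 12.011, 15.999 u) on an
equilateral 2.5 Bohr frame; its internals are the three bond displacements
(x, y, s):

    V11 = a/2 (x+x0)² + b/2 y² + k_s/2 s²
    V22 = a/2 (x−x0)² + b/2 y² + k_s/2 s² + Δ        V12 = c·y

with defaults a = 0.058, b = 0.05, c = 0.010 Ha/Bohr², Δ = 0.012 Ha,
x0 = 0.15 Bohr, k_s = 0.05. x is the tuning mode, y the coupling mode, s a
harmonic spectator. The surfaces are exactly degenerate at
(x*, 0, 0) = (Δ/(2a·x0), 0, 0); the coupling diverges like the inverse
distance to that seam while the smoothed coupling stays bounded, and the
lower-state eigenvector flips sign around a loop encircling it (a
Berry-phase signature, checked in the tests). The parameters place the
seam slightly beyond the classical turning point of vertically excited
Wigner ensembles, so trajectories probe the strong-coupling region without
stepping into the exact degeneracy — chosen so that the standard 0.5 fs
surface-hopping step resolves every passage (measured total-energy drift
≤ 1e-4 Hartree over 100 fs). A 1D avoided-crossing model and a 3-state
extension cover the remaining test needs.

Initial conditions are harmonic Wigner samples of the declared
ground-state well: per declared mode, position and momentum are drawn with
σ_q² = 1/(2mω) and σ_p² = mω/2. The declared modes are single-atom bond
displacements — an idealization of the true normal modes, adequate for an
ensemble generator and exactly testable.

What the generator does **not** emulate: anharmonicity of real ground
states, many-atom conformational complexity, state crossings involving
more than two states at once, and quantum-chemistry noise other than sign
scrambling. Passing tests therefore demonstrate the correctness of the
machinery (symmetries, derivatives, phase handling, hopping algebra,
statistics), not chemical accuracy on real molecules.

## Fewest-switches surface hopping

Nuclei follow velocity Verlet on the active adiabatic surface. Electronic
coefficients obey, in the adiabatic basis,

    i ċ_j = E_j c_j − i Σ_k (v · C_jk) c_k ,

integrated with 25 unitary substeps per nuclear step (matrix exponential
via eigendecomposition of the Hermitian H = diag(E) − i(v·C)), with E and
v·C linearly interpolated between the nuclear endpoints. Norm is conserved
to machine precision. Hop probabilities per nuclear step are the standard
fewest-switches expression

    g_{a→j} = max(0, 2 Δt Re[c_a* c_j (v·C_aj)] / |c_a|²),

clamped and renormalized if their sum exceeds one; the target is drawn by
inverse CDF against a single uniform variate. Accepted hops rescale the
velocity along the classical coupling vector, solving the quadratic that
conserves total energy exactly (the root of smaller magnitude is taken);
insufficient projected kinetic energy makes the hop frustrated (velocities
unchanged by default, or reflected along the coupling direction).
Energy-based decoherence damping (constant C = 0.1 Hartree) is on by
default. Because the oracle's eigenvector signs are fixed pointwise, not
continuously, each coupling vector is re-aligned with its previous-step
direction per trajectory and pair before entering the electronic
propagation — without this, sign-convention jumps corrupt the coefficient
evolution exactly in the strong-coupling regions.

Every trajectory's total energy is monitored; when the drift from its
initial value exceeds a bound (default 0.2 eV) the trajectory is flagged
invalid and excluded from ensemble populations from that time onward.
Ensembles propagate in lockstep so a learned surface is evaluated on the
whole batch at every step. Populations are fractions of active states
among valid trajectories, with binomial standard errors. Excited-state
lifetimes come from least-squares fits of the closed-form sequential
first-order chain S_{S−1} → … → S_0 (Bateman solution; exact rate ties are
split by a 1e-8 relative perturbation; flat populations at 1 return an
infinite-lifetime flag, other flat inputs are rejected as
non-identifiable).

## Spectra

Vertical absorption spectra use `f = (2/3)·ΔE·‖μ_ij‖²` (atomic units) per
upward transition and Gaussian broadening with a fixed full width at half
maximum (default 0.1 eV); ensemble spectra average equally over the input
geometries. The broadened integral equals the summed oscillator strength;
a too-narrow grid triggers a warning with the truncated mass fraction.
Non-upward predicted transitions (possible for an imperfect model) are
skipped with a warning.

## Error maps

2D scans over two internal coordinates of a synthetic model hold the
remaining coordinates fixed and record, per node, log10 of the mean
absolute component error (floored at 1e-12 before the logarithm), with
coupled properties phase-aligned per node; averaging is over components
first, then over seeds when maps from several training seeds are combined.
Difference maps subtract two models' maps node by node and are
antisymmetric under swapping the models.

## The benchmark study

`namdnn.benchmark` pins the study conditions used by the test suite and by
`scripts/acceptance.py`: 2500 samples of `ci2d` drawn uniformly over the
internal-coordinate box with phase corruption 1.0, split 2000/250/250;
equivariant+direct vs invariant+derivative comparison models (32 features,
3 blocks); training budget 60 epochs, Adam lr 1e-2, batch 250, plateau
decay 0.7 every 20 flat epochs, phase-vector loss, weights 1.0 for
energies, forces and couplings. At this budget both families reach
held-out MAEs of a few 1e-4 Ha (energies), below 1e-3 Ha/Bohr (forces) and
around 1e-3 a.u. (smoothed couplings), and the equivariant model's
coupling error is consistently the lower one across seeds — consistent
with the direct vectorial head not being constrained to curl-free fields.

Two further configurations serve the downstream applications:

* the **production dynamics surface** — the equivariant family widened to
  48 channels at the same budget. The extra width mainly sharpens the
  model in the small-gap region that controls hopping; it is what the
  exact-vs-learned population comparison runs on (200 trajectories,
  100 fs at 0.5 fs, identical Wigner initial conditions and random
  streams, agreement within binomial error).
* the **spectra model** — energies and dipoles only. A Franck–Condon
  spectrum needs nothing else, the training is much cheaper without the
  derivative-based heads, and keeping the large permanent-dipole targets
  out of the dynamics model's loss protects its coupling accuracy (at
  weight 1 they dominate the loss scale). This split mirrors the common
  practice of keeping transition dipoles out of the propagation itself.

## Known limitations

* The autodiff engine implements exactly the operations the networks need;
  it is not a general-purpose framework and holds whole batches in memory.
* Phase-vector enumeration is exponential in S (enforced cap S ≤ 12).
* The FSSH implementation is a single standard variant (adiabatic basis,
  NAC-direction rescaling, energy-based decoherence); spin–orbit coupling,
  field coupling and alternative hopping schemes are out of scope.
* Lifetime fits assume a strictly sequential first-order chain; branching
  or reversible kinetics are not modelled (populations that plateau, e.g.
  from frustrated-hop equilibration, fit poorly and show a large
  residual).
* The synthetic models have at most three internal degrees of freedom;
  conclusions about representation quality on real high-dimensional
  molecules do not follow from this study alone.
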