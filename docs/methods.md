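# Methods

This note documents the models and procedures implemented in
`deltakern`, the defaults and why they were chosen, what the synthetic
fixtures do and do not emulate, and the numerical choices that matter.

## The Δ-learning model

**Normalization.** Raw quantum-chemical total energies are dominated by
per-element atomic contributions. Both energy columns (baseline and
reference) are therefore regressed on the composition vector
(H, C, N, O, F, S counts, fixed in that order everywhere) with an
intercept; the learning target is the difference of the residuals. The
regression coefficients play the role of free-atom energies, so the
residuals are atomization-like energies and the two readings of the
target — "difference of normalized energies" and "difference of
atomization energies" — coincide. Elements absent from the training
data get no coefficient and are reported as undetermined (coefficient
pinned at 0); the intercept keeps residuals exactly zero-mean.

Three normalization modes exist in `train()`:

* `separate` (default) — one regression per energy column, fitted
  before the kernel stage; the literal two-stage procedure.
* `joint` — a single regression of the raw energy difference.
* `coupled` — composition coefficients and kernel weights solved in one
  least-squares system on the raw energy difference, ridge on the
  kernel weights only.

All three give near-identical *total* predictions. They differ sharply
for the **per-atom decomposition**: with two-stage residual targets the
kernel weights must reproduce `P⊥ K α_true` (the projector `P⊥` removes
the composition span), which forces large mutually-cancelling weights
whose per-atom pattern is essentially noise. In a controlled experiment
with the planted-correction fixtures, the two-stage fit recovers the
planted amplitudes poorly even when the basis contains the exact
planted environments, while the coupled fit recovers them to numerical
precision and reaches Pearson r ≈ 0.99 between predicted and planted
per-atom corrections on held-out structures (element-centred, since any
composition regression absorbs per-element constants). Use `coupled`
whenever atomic attribution matters (e.g. the correction field);
totals-oriented work can stay with the default.

**Kernel.** Gaussian, `k(x, x′) = exp(−‖x−x′‖²/2σ²)`, σ = 3 in
descriptor-space units, restricted to same-element pairs (standard
practice for element-tagged local kernels). Training solves the
ridge-regularised least-squares problem over structure-level features
`K[s, j] = Σ_{i∈atoms(s)} k(x_i, x_j)` via a stacked (augmented)
least-squares system — numerically stabler than normal equations at
tiny ridge. Ridge defaults to 1e-8; at `ridge=0` a singular system
raises with advice rather than silently returning a minimum-norm
solution. Sample weights are supported and flow into the normalization
fits as well, so duplicating a record is exactly equivalent to doubling
its weight.

**Descriptor.** The representation is a *contract*: element-tagged,
fixed-length, invariant under rigid motion and same-element
permutation, smoothly cut off, and local. The default implementation
expands each atom's neighbourhood in element-resolved radial Gaussians
(24 centres from 0.5 Å to the 5 Å radial cutoff) times the smooth
cutoff `f_c(r) = (cos(πr/r_c)+1)/2`, plus element-pair-resolved
Gaussians over the cosine of the bond angle (12 centres on [−1, 1]) with
cutoff factors at the 4 Å angular cutoff. Length is a deterministic
function of the config (6·n_radial + 21·n_angular per atom), and
persisted descriptor matrices carry a config-hash sidecar so matrices
from different configs cannot be silently mixed. Gradients are not
provided — nothing in the toolkit needs forces (sampling is Monte
Carlo). An adapter producing the same `(N, D)` layout can substitute an
external descriptor for large-scale parity work. Unit tests use a
compact 8×6 basis; the contract, not the basis size, is what the
downstream math relies on.

**Selection.** FPS is greedy max–min in Euclidean descriptor space,
deterministic: the start point is the point farthest from the centroid
("max-norm") and ties break on the lowest index. Per-element quotas
default to the 40 000-environment budget (H 5000, C 12000, N 8000,
O 8000, F 2000, S 5000) scaled proportionally (largest-remainder
rounding) when the pool is smaller, and clamp with a logged warning
rather than erroring so full-scale configurations run on small
fixtures. OMP is classical: correlation screening on unit-normalised
columns, full refit of the active weights each step, joint across
elements (the basis budget is global). The fast path works on the Gram
matrix; residual norms are recomputed explicitly to avoid cancellation
error near exact recovery. Candidates numerically dependent on the
active set (last Cholesky pivot below max(10·ridge, 1e-12)) are dropped
with a warning.

## The sampler

resH–RE runs one chain per λ on `V = (1−λ)V_target + λV_baseline` at a
single temperature (default 300 K, k_B = 1.987204259e-3 kcal/mol/K).
Default ladder: six λ values linear on [0, 1]. Moves displace every
Cartesian coordinate by N(0, σ_step²); σ_step defaults to 0.001 Å (the
molecular-scale choice; toy potentials want ~0.3 Å and the fixture
helpers use such values). Exchanges follow the standard
Hamiltonian-RE Metropolis criterion on nearest-neighbour pairs,
alternating even/odd sweeps every 20 steps; `n_steps` counts
per-replica move attempts, exchanges are extra events. The λ = 1 slot
may be replaced by a canonical reservoir treated as an infinite bath: a
fresh uniform draw replaces the MC move, nothing is ever written back.
Per-replica RNG streams are spawned from the master seed, so runs are
bit-reproducible; no auto-tuning of the step size is performed by
default (a flag exists, off).

One practical caveat surfaced by testing: the reservoir must itself be
a well-decorrelated canonical sample. A short or correlated reservoir
biases the *entire* ladder through the exchange chain — the fixture
reservoir generator therefore subsamples a long Metropolis chain at a
large stride (default 50; population-sensitive tests use 300) after
burn-in, and its output is checked against quadrature.

## Free-energy surfaces

`d` is the minimum distance from the designated nitrogen to any atom of
the blocking group; `θ` is the signed distance from the nitrogen to the
plane through the three atoms bonded to it. The sign convention is
explicit and serialized: with an `orientation_reference` atom the
normal points towards it (making θ invariant under both proper and
improper rigid motions); without one, the right-hand rule on the
plane-atom ordering applies and θ flips under mirror reflection.
Collinear plane atoms (triangle area ≤ 1e-6 Å²) raise a geometry error.

`F = −k_B T ln(counts)` per bin, gauge-shifted so the occupied-bin
minimum is exactly 0; empty bins are +inf, never a finite fill value.
Default grid 60×60 over the data range padded 5 %. Basin ΔG defaults to
the integrated-population route, `ΔG(A,B) = k_B T ln(P_A/P_B)`
(positive = A more stable, antisymmetric); a minimum-depth mode exists
behind a flag since surfaces are sometimes compared that way, and a
log-sum-exp re-derivation from the free-energy grid is kept as an
independent algebraic path (the two agree to 1e-10 by construction).

## Correction fields

`field(r) = Σ_i c_i G(r − r_i; w)` with unit-integral 3D Gaussians,
default width 1 Å, spacing 0.2 Å, padding 4 Å. Unit normalization makes
the grid integral equal the summed corrections (within 1 % for spacing
≤ width/4), so isovalue magnitudes are energy densities; the default
isovalue pair ±10 is configurable and no claim is made about unit
equivalence with any externally rendered figure. Export is Gaussian
cube with the header converted to Bohr as the format requires; the
bundled reader is for round-trip checking.

## Synthetic fixtures — what they do and do not show

The generator produces random clusters (4–8 atoms by default, element
weights favouring H and C, minimum interatomic distance 0.8 Å, a few
relaxation steps under the baseline) labelled by a pairwise-Morse
baseline plus per-element atomic offsets; reference labels add
different offsets and a planted correction built from Gaussian bumps
*in descriptor space* with width equal to the kernel σ — exactly the
model's hypothesis class, so recovery experiments isolate the estimator
from representation error. An off-class three-body correction is
available to probe graceful degradation, and optional iid Gaussian
label noise emulates reference-level noise. Analytic potentials
(tilted 1D double well with harmonic confinement, 2D Gaussian well,
harmonic net) ship quadrature oracles for populations and moments.

What passing these tests shows: the estimator, selection, sampler and
analysis machinery are correct and internally consistent. What they do
not show: accuracy on real molecules — real DFTB→DFT corrections are
not exactly in the hypothesis class, real conformer ensembles are far
more structured than random clusters, and no claim about transferable
chemical accuracy follows from fixture recovery.

## Problem sizes and numerical choices

* Acceptance-style checks in the test suite run at: 50 structures for
  the full-kernel interpolation oracle; 10 pools × (12 candidates, 20
  structures) for OMP-oracle agreement; 20 pools ≤ 100 points for FPS;
  2500 structures (2000 train) with an OMP basis of 200 for the
  planted-correction recovery and its learning curve; 10⁶ steps for the
  six-replica double-well run; 10⁵ steps for the end-to-end pipeline.
  `scripts/acceptance.py` uses 1200 structures (800 train, OMP 120),
  3×10⁵ sampler steps and a 2×10⁴-step pipeline — sizes chosen so a
  full reproduction stays around a minute while every quantity remains
  statistically meaningful.
* Stochastic assertions use blocked standard errors (block means over
  the snapshot stream) rather than assuming independent samples, and
  statistical tests (KS, χ², normality) run at α = 0.01 on subsampled,
  fast-mixing chains.
* Tolerances: exact-interpolation and dual-solver agreement at 1e-6 /
  1e-8 (comparing fitted values, which are well-conditioned even when
  the weights are not); invariance checks at 1e-8; extensivity and
  additivity at 1e-6 over 200–500 Å separations (the Morse tail and the
  descriptor cutoff both vanish identically there).

## Known limitations

* The default descriptor is not numerically equal to any published
  descriptor family; σ = 3 is kept as the kernel default but its
  resolving power depends on the descriptor's distance scale.
* Per-atom attribution is only identifiable in `coupled` mode and only
  up to per-element constants; sparse (OMP) bases trade some
  attribution fidelity for speed (r ≈ 0.86 at a basis of 200 vs 0.99
  for a full basis in the recovery experiment).
* The sampler is serial; parallel replicas are an implementation
  freedom deliberately not taken (reproducibility is the contract).
* No forces, no molecular dynamics, no WHAM/MBAR reweighting across λ —
  only the λ = 0 stream is analysed.
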