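# deltakern

Δ-learning kernel potentials for flexible organic molecules, with
replica-exchange Monte Carlo sampling and conformational free-energy
analysis.

Mapping the conformational free-energy surface (FES) of a flexible
functional molecule — a photoswitchable organocatalyst, say — needs both
an energy function of near-hybrid-DFT quality and millions of sampling
steps. Semiempirical baselines (DFTB-type methods) are cheap enough to
sample but systematically wrong; hybrid DFT is accurate but far too
expensive. `deltakern` implements the Δ-learning route between the two:

1. **Normalization.** Both energy columns are regressed on element
   counts, `E ≈ Σ_e c_e N_e + b` (multilinear regression over H, C, N,
   O, F, S), so the learning target is the atomization-like residual.
2. **Δ target.** For each structure *s*,
   `Δ(s) = Ẽ_ref(s) − Ẽ_base(s)` (normalized reference minus normalized
   baseline, kcal/mol).
3. **Sparse local kernel regression (LKR).** The correction is a sum of
   atomic contributions against a sparse basis of stored atomic
   environments `x_j`:

   `Δ̂(s) = Σ_{i∈atoms(s)} Σ_j α_j k(x_i, x_j)`,
   `k(x, x′) = exp(−‖x − x′‖² / 2σ²)` (σ = 3, same-element pairs only).

   Environments are described by an element-tagged radial + angular
   expansion with a 5 Å radial and 4 Å angular cutoff (a pluggable
   contract — any invariant, smoothly cut-off local descriptor works).
4. **Selection.** Farthest point sampling builds a diverse per-element
   environment pool (quota ratios H:C:N:O:F:S = 5000:12000:8000:8000:
   2000:5000, scaled to the data); orthogonal matching pursuit (OMP)
   greedily picks the basis environments most correlated with the
   residual, refitting all active weights each step.
5. **Sampling.** Reservoir–Hamiltonian replica exchange (resH–RE):
   six replicas sample `V = (1−λ)V_target + λV_baseline` with λ linear
   on [0, 1] at one temperature; moves are global Gaussian displacements
   with Metropolis acceptance, nearest-neighbour exchanges every 20
   steps, and the λ = 1 slot is fed by a canonical reservoir of baseline
   samples treated as an infinite bath.
6. **Analysis.** The λ = 0 stream is histogrammed over two collective
   variables — `d`, the shortest nitrogen-to-blocking-group distance,
   and `θ`, the signed nitrogen-to-plane (pyramidalization) distance —
   and Boltzmann-inverted, `F = −k_B T ln ρ`, with basin free energies
   from integrated populations. Per-atom corrections can be smeared into
   a volumetric scalar field and exported as a Gaussian cube.

Everything is testable without external electronic-structure engines:
the `fixtures` module generates random relaxed clusters, analytic toy
potentials with quadrature oracles, and datasets whose reference labels
carry a *planted* correction lying exactly in the kernel model's
hypothesis class.

## Worked example

`examples/01_train_delta_model.py` builds 600 labelled clusters, trains
on 480 of them (FPS pool of 400 environments, OMP basis of 120) and
evaluates on the held-out 120:

```
planted correction spread (sd):      4.132 kcal/mol
baseline-only test MAE:              1.351 kcal/mol
corrected test MAE:                  0.404 kcal/mol
corrected R^2 / slope:              1.0000 / 1.0000
```

The baseline-only row is the honest "no ML" comparison (composition
regression applied, zero kernel correction); the corrected MAE sits well
below both it and the spread of the planted signal, i.e. the sparse
model recovered the correction rather than memorising compositions.
`examples/02_resh_re_sampling.py` (sampler vs. quadrature),
`03_free_energy_surface.py` (FES + basin ΔG) and
`04_correction_field.py` (cube export) walk the remaining capabilities.

## Command line

A thin CLI wraps the library:

```sh
deltakern fixtures molecules --n 500 --seed 1 mols.extxyz
deltakern fixtures labels mols.extxyz labelled.extxyz
deltakern train --omp-m 200 labelled.extxyz model.npz
deltakern predict model.npz labelled.extxyz
deltakern sample --model-path model.npz --replicas 6 start.extxyz traj/
deltakern fes traj/replica_0.extxyz cv_spec.json fes.dat
deltakern basins fes.dat
deltakern field model.npz structure.extxyz field.cube
deltakern pipeline --seed 1 out/        # fixtures→train→sample→FES→field
```

Structures travel as multi-frame extended XYZ with `e_baseline` /
`e_reference` key=value labels on the comment line (key names are
configurable); units are Å and kcal/mol throughout.

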