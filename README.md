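# scpkaczmarz

Sparsity-constrained preconditioned Kaczmarz (SCP-Kaczmarz) reconstruction
for fluorescence molecular tomography (FMT), with a 2D diffusion-approximation
forward simulator and a synthetic phantom generator, so every claim about the
solver can be tested end-to-end without external data.

## The problem

FMT reconstructs the spatial distribution of a fluorescent marker inside
tissue from light measured on the boundary under laser excitation.  After
discretisation the measurement model is linear,

    phi_m = A x,        A in R^(M x N),  M < N,

where `x` is the nodal fluorescent yield and `A` the Born sensitivity matrix
derived from two coupled diffusion equations (excitation and emission
wavelengths) with a Robin boundary condition.  Because photons diffuse, the
rows of `A` are strongly correlated and the problem is severely ill-posed;
row-action solvers such as Kaczmarz (ART) converge very slowly on it.

## The method

SCP-Kaczmarz combines two ideas:

1. **Row-orthogonalising preconditioner.**  From the SVD `A = U S V^T`, the
   matrix `W = (S S^T + lambda I)^(-1/2) U^T` makes the rows of `B = W A`
   mutually orthogonal (`B B^T = I_M` for `lambda = 0` and full row rank), so
   a single sequential Kaczmarz sweep

       x <- x + B_i^T (y_i - B_i x) / (B_i B_i^T),   i = 1..M,  y = W phi_m

   solves a consistent system exactly instead of creeping along correlated
   hyperplanes.

2. **Sparsity-matched thresholding.**  Fluorescent probes accumulate in
   small regions, so after every sweep the iterate is hard-thresholded,
   keeping entries `x_n >= beta * max(x)`, with `beta` chosen so the Hoyer
   sparseness

       sparsity(x) = (sqrt(N) - ||x||_1 / ||x||_2) / (sqrt(N) - 1)

   of the result is as close as possible to a preset wanted value `psi`
   (1 = single nonzero, 0 = all entries equal).  The step doubles as a
   nonnegativity projection.  `psi` can be set from an estimated
   target-to-domain volume fraction (`wanted_sparsity_from_fraction`).

The package also ships the classical Kaczmarz baseline, the evaluation
metrics (relative deviation, Dice variants, localisation error), MatrixMarket
/CSV readers and writers, and a thin CLI
(`scpkaczmarz simulate | precondition | reconstruct | evaluate`).

## Worked example

`examples/two_target_reconstruction.py` simulates a 20 mm x 20 mm slab of
muscle-like tissue (32 x 32 grid), two 1 mm fluorescent disks, five boundary
point sources and detectors on every boundary node, then reconstructs with
both solvers:

```
system: M = 620 measurements, N = 1024 unknowns
        SCP-Kaczmarz: delta = 0.189  support Dice = 1.00  sparsity = 0.901  localisation error = 0.04 mm
  classical Kaczmarz: delta = 0.935  support Dice = 0.20  sparsity = 0.361  localisation error = 0.89 mm
sweeps for SCP to reach delta <= 0.3: 9
classical delta after 100 sweeps:     0.935
```

`delta` is the relative deviation `||x_r - x_t||_2 / ||x_t||_2`; the support
Dice scores the overlap of reconstructed and true targets at half maximum
(1 = perfect localisation).  The constrained, preconditioned solver pins both
disks in nine sweeps; the baseline has barely moved after one hundred.

The other examples are single-topic: `examples/sparsity_measure.py` (the
Hoyer measure and the volume-fraction heuristic for `psi`) and
`examples/preconditioned_one_sweep.py` (one-sweep convergence and row
coherence before/after preconditioning).

The same pipeline is available from the shell:

```sh
scpkaczmarz simulate --config scenario.txt --out-dir sim/
scpkaczmarz reconstruct --matrix sim/A.mtx --measurements sim/phi_m.csv \
    --psi 0.9 --out x.csv --trace trace.csv
scpkaczmarz evaluate --recovered x.csv --truth sim/x_true.csv \
    --config scenario.txt --out report.csv
```

## Notes

See `docs/methods.md` for the model equations, discretisation, parameter
defaults, the noise model, and known limitations (in particular how
measurement noise bounds the attainable reconstruction error).
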