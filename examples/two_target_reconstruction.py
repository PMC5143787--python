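"""Full pipeline: simulate a two-disk phantom, reconstruct, evaluate.

Simulates a 20 mm x 20 mm tissue slab (homogeneous muscle optics, 32 x 32
grid) with two 1 mm fluorescent disks, five point sources one transport mean
free path beneath the surface, and detectors on every boundary node.  With
noise-free measurements, the sparsity-constrained preconditioned Kaczmarz
solver localises both disks within a handful of sweeps, while the classical
(unpreconditioned, unconstrained) Kaczmarz baseline barely moves in the same
budget.  delta is the relative deviation ||x_r - x_t|| / ||x_t||; the support
Dice counts overlap of the reconstructed and true targets at half maximum.
"""

from scpkaczmarz import (
    SolverConfig,
    classical_kaczmarz,
    evaluate,
    make_scenario,
    scp_kaczmarz,
    two_target_config,
)

bundle = make_scenario(two_target_config(noise_level=0.0))
A, phi, x_true = bundle.A.entries, bundle.phi_m, bundle.x_true
print(f"system: M = {A.shape[0]} measurements, N = {A.shape[1]} unknowns")

cfg = SolverConfig(wanted_sparsity=0.9, max_iterations=100, tolerance=0.0)
x_scp, trace = scp_kaczmarz(A, phi, cfg, x_true=x_true)
x_cls, trace_cls = classical_kaczmarz(A, phi, cfg, x_true=x_true)

grid = bundle.A.grid
for name, x in (("SCP-Kaczmarz", x_scp), ("classical Kaczmarz", x_cls)):
    r = evaluate(x, x_true, grid=grid)
    print(
        f"{name:>20}: delta = {r.relative_deviation:.3f}  "
        f"support Dice = {r.support_dice:.2f}  sparsity = {r.sparsity:.3f}  "
        f"localisation error = {r.localization_error:.2f} mm"
    )
print(f"sweeps for SCP to reach delta <= 0.3: {trace.first_iteration_below(0.3)}")
print(f"classical delta after 100 sweeps:     {trace_cls.delta[-1]:.3f}")
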