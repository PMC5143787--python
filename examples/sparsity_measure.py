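"""Hoyer sparseness measure and the wanted-sparsity heuristic.

Builds length-300 vectors with 1, 10 and 30 equal nonzeros, scores them with
the Hoyer measure (sqrt(N) - ||x||_1/||x||_2) / (sqrt(N) - 1), and shows how
the same numbers arise from an estimated target-to-domain volume fraction.
A value of 1 means a single nonzero (extremely sparse); 0 means all entries
equal (not sparse at all).
"""

import numpy as np

from scpkaczmarz import hoyer_sparsity, wanted_sparsity_from_fraction

for k in (1, 10, 30):
    x = np.zeros(300)
    x[:k] = 1.0
    print(f"{k:>2} nonzeros of 300 -> sparsity {hoyer_sparsity(x):.4f}")

# If a fluorescent target is believed to occupy ~3.3% of the imaging domain,
# the wanted sparsity psi handed to the solver is the measure of a uniform
# vector with that many nonzero nodes:
psi = wanted_sparsity_from_fraction(10 / 300, 300)
print(f"volume fraction 10/300 -> wanted sparsity psi = {psi:.4f}")
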