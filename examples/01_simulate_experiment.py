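"""Simulate one TF-induction experiment on a known regulatory network.

Builds a sparse ground-truth network, forces a ~50-fold induction of one
regulator, integrates every other gene's response, and prints the sampled
timecourses of the induced gene and its direct targets.
"""

import numpy as np

import inducekit as ik

net = ik.generate_network(n_genes=20, n_regulators=4, sparsity=0.03, seed=1)
induced = net.regulators[0]
design = ik.InductionDesign("demo", induced)
cube = ik.simulate_induction(net, design)

targets = [t for (t, r) in net.edge_set() if r == induced]
print(f"induced gene: {induced}; direct targets: {targets}")
print("\nexpression ratios (1 = steady state) at the sampled times:")
print(cube.exp_matrix("demo").loc[[induced] + targets].round(2).to_string())
print(
    "\nThe induced gene saturates near 50x within ~10 min; each target "
    "drifts away from 1 at a speed set by its network coefficient (positive "
    "coefficients rise, negative ones fall)."
)
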