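"""Recover a regulatory network from simulated induction experiments.

Simulates 20 induction experiments over a 50-gene network with 10
regulators, fits the per-gene sparse dynamical regression, and scores the
recovered edges against the ground truth, including the experiment-label
permutation negative control and a plain expression-on-expression LASSO
baseline.
"""

from inducekit.benchmark import edge_recovery_benchmark

res = edge_recovery_benchmark(
    n_genes=50, n_regulators=10, sparsity=0.02, n_experiments=20,
    noise_sd=0.1, seed=5,
)
print(f"edge-recovery AUROC:        {res['auroc']:.3f}")
print(f"permutation control AUROC:  {res['permutation_auroc_mean']:.3f}")
print(f"baseline LASSO AUROC:       {res['baseline_auroc']:.3f}")
top = res["model"].edge_scores().head(5)
truth = res["network"].edge_set()
top["true_edge"] = [(t, r) in truth for t, r in zip(top.target, top.regulator)]
print("\nstrongest recovered edges:")
print(top.to_string(index=False))
print(
    "\nRanking candidate edges by |coefficient| separates true from false "
    "edges (AUROC near 1); shuffling which experiment each response came "
    "from collapses recovery to chance (~0.5), and the dynamical model "
    "beats the static expression-on-expression baseline."
)
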