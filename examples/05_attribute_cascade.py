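"""Attribute an indirect response to its mediating regulator.

Simulates the relay A -> B -> D (A induced; B activates D), fits the
dynamical model, and decomposes D's rise into per-regulator marginal
contributions (psi). The attribution recovers B as the driver of D even
though only A was perturbed, then assembles the experiment-level causal
graph.
"""

import numpy as np

import inducekit as ik
from inducekit.attribution import attribute_marginal
from inducekit.benchmark import cascade_experiments, cascade_network

net = cascade_network()
cube, designs = cascade_experiments(net)
induced = {d.experiment_id: d.induced_gene for d in designs}
model = ik.fit_network(cube, induced_map=induced)
pred = ik.integrate_predictions(model, cube)

records = []
for gene in ("B", "D"):
    t, y = cube.timecourse(gene, "indA1")
    fit = ik.fit_and_select(t, np.log2(y), seed=1)
    interval = ik.extract_response_intervals(fit, (t[0], t[-1]))[0]
    rec = attribute_marginal(model, cube, pred, gene, "indA1", interval)
    records.append(rec)
    drivers = {r: round(float(rec.psi[r]), 2) for r in rec.drivers()}
    print(f"{gene} {interval.kind} over [{interval.t_start:.0f}, {interval.t_end:.0f}] min: "
          f"f_obs={rec.f_observed:.2f}, f_model={rec.f_model:.2f}, drivers psi={drivers}")

graph = ik.build_experiment_graph(records, de_genes=["B", "D"], induced_gene="A",
                                  experiment="indA1")
print("\ncausal graph edges:")
for u, v, d in graph.edges(data=True):
    w = "" if d["weight"] != d["weight"] else f" (psi={d['weight']:.2f})"
    print(f"  {u} -> {v} [{d['type']}]{w}")
print(
    "\npsi is each regulator's fractional share of the model-predicted log2 "
    "change over the response interval; shares above 0.2 define direct "
    "edges, while the induced gene is linked to every responder at least "
    "indirectly."
)
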