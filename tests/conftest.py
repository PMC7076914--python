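"""Shared fixtures: small simulated datasets with known ground truth."""

import warnings

import numpy as np
import pandas as pd
import pytest

import inducekit as ik
from inducekit.benchmark import cascade_experiments, cascade_network
from inducekit.containers import EXP, GENE, TIME, ExpressionCube

warnings.filterwarnings("ignore", message=".*Objective did not converge.*")

GRID = np.asarray(ik.DEFAULT_TIME_GRID)


def make_cube(values: np.ndarray, genes, experiments, grid=GRID) -> ExpressionCube:
    """Ratio-scale cube from an array shaped (genes, experiments, times)."""
    cols = pd.MultiIndex.from_product([experiments, grid], names=[EXP, TIME])
    mat = values.reshape(len(genes), -1)
    return ExpressionCube(pd.DataFrame(mat, index=pd.Index(genes, name=GENE), columns=cols))


@pytest.fixture(scope="session")
def small_network():
    return ik.generate_network(n_genes=20, n_regulators=4, sparsity=0.02, seed=11)


@pytest.fixture(scope="session")
def cascade():
    """Fully fitted A -> B -> D cascade: cube, model, predictions, designs."""
    net = cascade_network()
    cube, designs = cascade_experiments(net)
    induced = {d.experiment_id: d.induced_gene for d in designs}
    model = ik.fit_network(cube, induced_map=induced)
    predictions = ik.integrate_predictions(model, cube)
    return {
        "network": net,
        "cube": cube,
        "designs": designs,
        "induced": induced,
        "model": model,
        "predictions": predictions,
    }


@pytest.fixture(scope="session")
def artifact_sim():
    """Zero-noise multi-experiment simulation with 30 planted artifacts."""
    net = ik.generate_network(40, 8, 0.015, seed=21)
    designs = [
        ik.InductionDesign(f"e{j}", r, system_class="ZEV" if j % 2 else "GEV")
        for j, r in enumerate(net.regulators)
    ]
    cube = ik.simulate_experiment_set(net, designs)
    class_map = {d.experiment_id: d.system_class for d in designs}
    n_courses = len(cube.genes) * len(cube.experiments)
    spec = ik.NoiseSpec(
        gene_log_sd=0.0,
        array_log_sd=0.0,
        spot_log_sd=0.0,
        artifact_rates={k: 10 / n_courses for k in ("spot_disagreement", "spike", "crosstalk")},
        seed=31,
    )
    clean_spec = ik.NoiseSpec(gene_log_sd=0.0, array_log_sd=0.0, spot_log_sd=0.0, seed=31)
    spots, ledger = ik.render_spot_table(cube, spec)
    spots_clean, _ = ik.render_spot_table(cube, clean_spec)
    return {
        "network": net,
        "cube": cube,
        "class_map": class_map,
        "spots": spots,
        "spots_clean": spots_clean,
        "ledger": ledger,
    }
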