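"""Ground-truth network and induction-experiment simulator.

Every downstream stage of the pipeline (cleaning, kinetic fitting, network
regression, attribution) is benchmarked against data produced here, where
the true regulatory coefficients, the noise process, and every planted
measurement artifact are known exactly.

The generative dynamics reuse the same functional form the regression
module later fits -- the rate of change of ``ln y_i`` is a sparse linear
combination of regulator ratio-deviations ``(y_k - 1)`` plus
target-proportional terms ``(y_i*y_k - 1)/y_i`` -- so that coefficient
recovery is a well-posed question. The induced gene itself is exogenous:
it follows a forced logistic profile reaching ~50-fold within ~10 minutes,
normalized so it equals exactly 1 at t = 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import (
    DEFAULT_TIME_GRID,
    EXP,
    GENE,
    TIME,
    ExpressionCube,
    InductionDesign,
    NoiseSpec,
    TrueNetwork,
)

#: Integration aborts when |ln y| exceeds this bound.
LN_BOUND = 12.0

#: Multiplier applied when planting a spot-disagreement artifact (> 4x rule).
DISAGREEMENT_FACTOR = 5.0
#: Multiplier applied when planting a spike artifact (>= 4x up then down).
SPIKE_FACTOR = 6.0
#: Green-channel inflation used when planting a crosstalk artifact (> 8x rule).
CROSSTALK_FACTOR = 10.0

#: Baseline green-channel intensity (arbitrary units, well above the floor C).
BASE_INTENSITY = 1000.0


class SimulationDivergence(RuntimeError):
    """Raised when the ODE integration leaves the plausible dynamic range."""


# --------------------------------------------------------------------------
# network generation
# --------------------------------------------------------------------------

def generate_network(
    n_genes: int,
    n_regulators: int,
    sparsity: float,
    effect_scale: float = 1e-3,
    seed: int = 0,
    beta_fraction: float = 0.0,
    gene_ids: list | None = None,
) -> TrueNetwork:
    """Draw a sparse ground-truth network with designated regulator columns.

    ``round(sparsity * n_genes**2)`` edges (target, regulator) are placed
    uniformly at random in the columns of the first ``n_regulators`` genes,
    excluding the diagonal. Every edge receives an alpha coefficient of
    magnitude ``Uniform(0.5, 1.5) * effect_scale`` with a random sign; a
    ``beta_fraction`` subset additionally receives a beta coefficient of
    the same scale.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    if n_regulators > n_genes:
        raise ValueError("n_regulators cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        width = len(str(n_genes))
        gene_ids = [f"g{idx:0{width}d}" for idx in range(n_genes)]
    regulators = list(gene_ids[:n_regulators])

    n_edges = int(round(sparsity * n_genes * n_genes))
    candidates = [(i, k) for k in range(n_regulators) for i in range(n_genes) if i != k]
    n_edges = min(n_edges, len(candidates))
    chosen = rng.choice(len(candidates), size=n_edges, replace=False)

    alpha = np.zeros((n_genes, n_genes))
    beta = np.zeros((n_genes, n_genes))
    for pos in chosen:
        i, k = candidates[pos]
        sign = rng.choice([-1.0, 1.0])
        alpha[i, k] = sign * rng.uniform(0.5, 1.5) * effect_scale
        if rng.random() < beta_fraction:
            beta[i, k] = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5) * effect_scale
    return TrueNetwork(gene_ids=list(gene_ids), alpha=alpha, beta=beta, regulators=regulators)


# --------------------------------------------------------------------------
# noise-free dynamics
# --------------------------------------------------------------------------

def induction_profile(t, design: InductionDesign) -> np.ndarray:
    """Forced expression ratio of the induced gene.

    A logistic rise re-anchored so the profile equals exactly 1 at t = 0 and
    approaches ``induction_fold`` asymptotically:
    ``y(t) = 1 + (F - 1) * (s(t) - s(0)) / (1 - s(0))`` with
    ``s(t) = expit(slope * (t - t_half))``.
    """
    t = np.asarray(t, dtype=float)
    s = expit(design.induction_slope_per_min * (t - design.induction_halftime_min))
    s0 = expit(-design.induction_slope_per_min * design.induction_halftime_min)
    return 1.0 + (design.induction_fold - 1.0) * (s - s0) / (1.0 - s0)


def simulate_induction(
    network: TrueNetwork,
    design: InductionDesign,
    integration_step_min: float = 0.1,
) -> ExpressionCube:
    """Integrate the noise-free response of the network to one induction.

    The induced gene follows :func:`induction_profile`; every other gene
    evolves by ``d ln y_i/dt = sum_k alpha_ik (y_k - 1)
    + beta_ik (y_i y_k - 1)/y_i`` with explicit fixed-step Euler updates in
    ln-space (which guarantees positivity), sampled at the design's grid.
    """
    if design.induced_gene not in network.gene_ids:
        raise ValueError(f"induced gene {design.induced_gene!r} not in network")
    grid = design.grid
    if integration_step_min > np.min(np.diff(grid)):
        raise ValueError("integration step must not exceed the smallest grid spacing")

    gene_ids = network.gene_ids
    n = len(gene_ids)
    induced_idx = gene_ids.index(design.induced_gene)
    alpha, beta = network.alpha, network.beta

    z = np.zeros(n)  # ln y, all genes at steady state
    out = np.empty((n, len(grid)))
    out[:, 0] = 1.0

    beta_rowsum = beta.sum(axis=1)

    def deriv(z_state, t_now):
        # d z_i/dt = sum_k alpha_ik (y_k - 1) + beta_ik (y_i y_k - 1)/y_i
        #          = [alpha (y - 1)]_i + [beta y]_i - (sum_k beta_ik)/y_i
        y = np.exp(z_state)
        y[induced_idx] = induction_profile(t_now, design)
        rate = alpha @ (y - 1.0) + beta @ y - beta_rowsum / y
        rate[induced_idx] = 0.0
        return rate

    h = float(integration_step_min)
    t = 0.0
    for m in range(1, len(grid)):
        n_steps = int(round((grid[m] - grid[m - 1]) / h))
        step = (grid[m] - grid[m - 1]) / n_steps
        for _ in range(n_steps):
            k1 = deriv(z, t)
            k2 = deriv(z + 0.5 * step * k1, t + 0.5 * step)
            k3 = deriv(z + 0.5 * step * k2, t + 0.5 * step)
            k4 = deriv(z + step * k3, t + step)
            z = z + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += step
            if np.any(np.abs(z) > LN_BOUND):
                bad = gene_ids[int(np.argmax(np.abs(z)))]
                raise SimulationDivergence(
                    f"|ln y| exceeded {LN_BOUND} for gene {bad!r} at t={t:.2f} min"
                )
        y = np.exp(z)
        y[induced_idx] = induction_profile(grid[m], design)
        out[:, m] = y

    cols = pd.MultiIndex.from_product([[design.experiment_id], grid], names=[EXP, TIME])
    return ExpressionCube(pd.DataFrame(out, index=pd.Index(gene_ids, name=GENE), columns=cols))


def simulate_experiment_set(
    network: TrueNetwork,
    designs: list[InductionDesign],
    integration_step_min: float = 0.1,
    hide_genes: list | None = None,
) -> ExpressionCube:
    """Simulate several experiments and concatenate them into one cube.

    ``hide_genes`` drops genes from the *output* while they still act in the
    dynamics -- an unobserved-regulator model-mismatch mode for robustness
    studies.
    """
    cubes = [simulate_induction(network, d, integration_step_min) for d in designs]
    values = pd.concat([c.values for c in cubes], axis=1)
    if hide_genes:
        values = values.drop(index=list(hide_genes))
    return ExpressionCube(values)


# --------------------------------------------------------------------------
# measurement corruption
# --------------------------------------------------------------------------

def corrupt_with_noise(
    cube: ExpressionCube,
    spec: NoiseSpec,
    class_map: dict | None = None,
) -> ExpressionCube:
    """Apply stress signature and log-normal noise, renormalized at t = 0.

    ``observed = true * stress(t) * exp(eps)`` with
    ``eps ~ N(0, gene_sd^2 + array_sd^2)``; afterwards every timecourse is
    divided by its own t = 0 value so the observed cube again starts at
    exactly 1 (mirroring the ratio-to-time-zero normalization of the real
    assay).
    """
    rng = np.random.default_rng(spec.seed)
    values = cube.values.copy()
    gene_sd = np.array([spec.gene_sd(g) for g in values.index])

    for exp_id in cube.experiments:
        times = cube.times(exp_id)
        mat = values[exp_id].to_numpy(dtype=float)
        stress = np.ones_like(times)
        if class_map and spec.stress_signature:
            cls = class_map.get(exp_id)
            if cls in spec.stress_signature:
                stress = np.asarray(spec.stress_signature[cls], dtype=float)
                if stress.shape != times.shape:
                    raise ValueError(f"stress signature grid mismatch for class {cls!r}")
        total_sd = np.sqrt(gene_sd[:, None] ** 2 + spec.array_log_sd**2)
        eps = rng.standard_normal(mat.shape) * total_sd
        obs = mat * stress[None, :] * np.exp(eps)
        obs = obs / obs[:, [0]]  # renormalize: y = 1 at t = 0 by construction
        for j, tt in enumerate(times):
            values.loc[:, (exp_id, tt)] = obs[:, j]
    return ExpressionCube(values)


# --------------------------------------------------------------------------
# spot-level rendering with planted artifacts
# --------------------------------------------------------------------------

def _timecourse_keys(cube: ExpressionCube) -> list[tuple]:
    return [(g, e) for e in cube.experiments for g in cube.genes]


def render_spot_table(
    cube: ExpressionCube,
    spec: NoiseSpec,
) -> tuple[pd.DataFrame, dict]:
    """Expand a cube into per-spot red/green intensities with planted artifacts.

    Returns the spot table (gene, experiment, time_min, spot_index, red,
    green) and a ledger recording the exact position of every planted
    artifact:

    - ``spot_disagreement``: one spot's ratio multiplied by
      :data:`DISAGREEMENT_FACTOR` (so max/min spot ratio > 4);
    - ``spike``: all spots at one interior time multiplied by
      :data:`SPIKE_FACTOR` (a >= 4x move immediately reversed);
    - ``crosstalk``: the green channel of a whole timecourse inflated by
      :data:`CROSSTALK_FACTOR` at every t > 0.

    Events are planted on distinct timecourses, and each planting is checked
    against the corresponding detection rule on the corrupted table (with a
    redraw if dynamics would mask it), so the ledger is an exact answer key
    for the cleaning module.
    """
    rng = np.random.default_rng(spec.seed)
    n_spots = spec.spot_count

    # base spot-level table, no artifacts
    frames = []
    for exp_id in cube.experiments:
        times = cube.times(exp_id)
        mat = cube.exp_matrix(exp_id).to_numpy(dtype=float)
        n_genes, n_times = mat.shape
        spot_eps = rng.standard_normal((n_genes, n_times, n_spots)) * spec.spot_log_sd
        ratio = mat[:, :, None] * np.exp(spot_eps)
        green = np.full_like(ratio, BASE_INTENSITY)
        red = green * ratio
        idx = pd.MultiIndex.from_product(
            [cube.genes, times, range(n_spots)], names=[GENE, TIME, "spot_index"]
        )
        frame = pd.DataFrame(
            {"red": red.reshape(-1), "green": green.reshape(-1)}, index=idx
        ).reset_index()
        frame[EXP] = exp_id
        frames.append(frame)
    spots = pd.concat(frames, ignore_index=True)[[GENE, EXP, TIME, "spot_index", "red", "green"]]
    spots = spots.set_index([GENE, EXP, TIME, "spot_index"]).sort_index()

    courses = _timecourse_keys(cube)
    n_courses = len(courses)
    rates = spec.artifact_rates
    counts = {
        kind: int(round(rates.get(kind, 0.0) * n_courses))
        for kind in ("spot_disagreement", "spike", "crosstalk")
    }
    used: set[tuple] = set()
    ledger: dict[str, list] = {"spot_disagreement": [], "spike": [], "crosstalk": []}

    def draw_course():
        for _ in range(20 * n_courses):
            g, e = courses[rng.integers(n_courses)]
            if (g, e) not in used:
                return g, e
        raise RuntimeError("could not find a free timecourse for artifact planting")

    def medians(g, e):
        sub = spots.loc[(g, e)]
        ratio = np.maximum(sub["red"], 2.0) / np.maximum(sub["green"], 2.0)
        return ratio.groupby(level=TIME).median().sort_index()

    # (a) spot-disagreement: one spot moved by DISAGREEMENT_FACTOR
    for _ in range(counts["spot_disagreement"]):
        g, e = draw_course()
        times = cube.times(e)
        t = float(times[rng.integers(len(times))])
        spot = int(rng.integers(n_spots)) if n_spots > 1 else 0
        spots.loc[(g, e, t, spot), "red"] *= DISAGREEMENT_FACTOR
        used.add((g, e))
        ledger["spot_disagreement"].append(
            {"gene": g, "experiment": e, "time_min": t, "spot_index": spot}
        )

    # (b) spike: all spots at one interior time moved up (then back, by the data)
    for _ in range(counts["spike"]):
        for _attempt in range(50):
            g, e = draw_course()
            times = cube.times(e)
            t_idx = int(rng.integers(1, len(times) - 1))
            t = float(times[t_idx])
            before = medians(g, e).to_numpy()
            trial = before.copy()
            trial[t_idx] *= SPIKE_FACTOR
            up = trial[t_idx] / trial[t_idx - 1]
            down = trial[t_idx] / trial[t_idx + 1]
            if up >= 4.0 and down >= 4.0:  # detectable despite underlying dynamics
                spots.loc[(g, e, t), "red"] = (spots.loc[(g, e, t), "red"] * SPIKE_FACTOR).to_numpy()
                used.add((g, e))
                ledger["spike"].append({"gene": g, "experiment": e, "time_min": t})
                break
        else:
            raise RuntimeError("could not plant a detectable spike event")

    # (c) crosstalk: inflate green at every t > 0 of a timecourse
    for _ in range(counts["crosstalk"]):
        for _attempt in range(50):
            g, e = draw_course()
            times = cube.times(e)
            med = medians(g, e)
            post = med.loc[med.index > 0].to_numpy()
            # after inflation observed ratio becomes y/CROSSTALK_FACTOR
            log2_dev = np.abs(np.log2(post / CROSSTALK_FACTOR))
            if np.quantile(log2_dev, 0.3) > 1.0:  # both detection criteria will fire
                mask = [idx for idx in spots.loc[(g, e)].index if idx[0] > 0]
                for t, spot in mask:
                    spots.loc[(g, e, t, spot), "green"] *= CROSSTALK_FACTOR
                used.add((g, e))
                ledger["crosstalk"].append(
                    {"gene": g, "experiment": e, "times": [float(t) for t in times if t > 0]}
                )
                break
        else:
            raise RuntimeError("could not plant a detectable crosstalk event")

    return spots.reset_index(), ledger
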