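"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionCube`, which stores relative
expression ``y`` for every (gene, experiment, time) triple on the ratio
scale: ``y = 1`` means "unchanged relative to the pre-induction steady
state", and every timecourse starts at exactly 1 at ``t = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE = "gene"
EXP = "experiment"
TIME = "time_min"
VALUE = "value"

#: Default sampling grid (minutes after inducer addition).
DEFAULT_TIME_GRID = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 90.0)

LN2 = np.log(2.0)


class ExpressionCube:
    """Relative expression values on a gene x (experiment, time) grid.

    Parameters
    ----------
    values
        DataFrame indexed by gene with a two-level column MultiIndex
        ``(experiment, time_min)``; entries are ratio-scale expression
        (positive, 1 at steady state).
    flags
        Optional dict of boolean DataFrames aligned with ``values``
        (e.g. ``"repaired"``, ``"crosstalk_repaired"``, ``"invariant"``).
    """

    def __init__(self, values: pd.DataFrame, flags: dict[str, pd.DataFrame] | None = None):
        if not isinstance(values.columns, pd.MultiIndex) or values.columns.nlevels != 2:
            raise ValueError("values must have (experiment, time_min) MultiIndex columns")
        values = values.sort_index(axis=1)
        if (values.to_numpy() <= 0).any():
            raise ValueError("expression ratios must be strictly positive")
        self.values = values
        self.flags = flags or {}

    # ------------------------------------------------------------------ views
    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def experiments(self) -> list:
        return list(self.values.columns.get_level_values(0).unique())

    def times(self, experiment) -> np.ndarray:
        return np.asarray(sorted(self.values[experiment].columns), dtype=float)

    def exp_matrix(self, experiment) -> pd.DataFrame:
        """Genes x times ratio matrix for one experiment."""
        return self.values[experiment].sort_index(axis=1)

    def timecourse(self, gene, experiment) -> tuple[np.ndarray, np.ndarray]:
        row = self.values.loc[gene, experiment].sort_index()
        return row.index.to_numpy(dtype=float), row.to_numpy(dtype=float)

    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)

    def copy(self) -> "ExpressionCube":
        return ExpressionCube(self.values.copy(), {k: v.copy() for k, v in self.flags.items()})

    # ------------------------------------------------------------------- I/O
    def to_long(self, log2: bool = False) -> pd.DataFrame:
        mat = self.log2() if log2 else self.values
        long = mat.stack([0, 1], future_stack=True).rename(VALUE).reset_index()
        long.columns = [GENE, EXP, TIME, VALUE]
        return long.sort_values([EXP, GENE, TIME], ignore_index=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame, log2: bool = False) -> "ExpressionCube":
        wide = long.pivot_table(index=GENE, columns=[EXP, TIME], values=VALUE, sort=True)
        if wide.isna().any().any():
            raise ValueError("long table does not form a complete gene x (experiment, time) grid")
        if log2:
            wide = np.power(2.0, wide)
        return cls(wide)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionCube({len(self.genes)} genes x {len(self.experiments)} experiments, "
            f"flags={sorted(self.flags)})"
        )


@dataclass
class TrueNetwork:
    """Ground-truth regulatory coefficients used by the simulator.

    ``alpha[i, k]`` is the linear effect of regulator ``k`` on the rate of
    change of ``ln y_i`` (units 1/min per unit ratio-deviation);
    ``beta[i, k]`` is the corresponding target-proportional effect.
    """

    gene_ids: list
    alpha: np.ndarray
    beta: np.ndarray
    regulators: list

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        n = len(self.gene_ids)
        if self.alpha.shape != (n, n) or self.beta.shape != (n, n):
            raise ValueError("alpha/beta must be square with one row/col per gene")
        if np.diag(self.alpha).any() or np.diag(self.beta).any():
            raise ValueError("self-edges are not generated: diagonal must be zero")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def edge_set(self) -> set[tuple]:
        """(target, regulator) pairs with any nonzero coefficient."""
        idx = np.argwhere((self.alpha != 0) | (self.beta != 0))
        return {(self.gene_ids[i], self.gene_ids[k]) for i, k in idx}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, k in np.argwhere((self.alpha != 0) | (self.beta != 0)):
            rows.append(
                {
                    "regulator": self.gene_ids[k],
                    "target": self.gene_ids[i],
                    "alpha": self.alpha[i, k],
                    "beta": self.beta[i, k],
                }
            )
        return pd.DataFrame(rows, columns=["regulator", "target", "alpha", "beta"])


@dataclass
class InductionDesign:
    """One induction experiment: which gene is forced and how it is sampled."""

    experiment_id: str
    induced_gene: str
    time_grid_min: tuple = DEFAULT_TIME_GRID
    system_class: str = "ZEV"
    induction_fold: float = 50.0
    induction_halftime_min: float = 5.0
    induction_slope_per_min: float = 1.0

    def __post_init__(self):
        grid = np.asarray(self.time_grid_min, dtype=float)
        if grid[0] != 0.0:
            raise ValueError("time grid must start at exactly 0")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("time grid must be strictly ascending")
        if self.induction_fold <= 1:
            raise ValueError("induction_fold must exceed 1")
        self.time_grid_min = tuple(grid)

    @property
    def grid(self) -> np.ndarray:
        return np.asarray(self.time_grid_min, dtype=float)


@dataclass
class NoiseSpec:
    """Measurement-corruption model for simulated cubes and spot tables.

    Noise is log-normal: multiplicative ``exp(eps)`` with
    ``eps ~ N(0, gene_sd^2 + array_sd^2)`` where the gene component may vary
    per gene and the array component is shared by all genes on one array
    (one (experiment, time) sample). ``stress_signature`` maps a system
    class (GEV/ZEV) to a ratio-scale multiplier per grid time applied to
    every gene of every experiment of that class.
    """

    gene_log_sd: float | dict = 0.1
    array_log_sd: float = 0.05
    stress_signature: dict = field(default_factory=dict)
    spot_count: int = 2
    spot_log_sd: float = 0.05
    artifact_rates: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        sds = self.gene_log_sd.values() if isinstance(self.gene_log_sd, dict) else [self.gene_log_sd]
        if any(s < 0 for s in sds) or self.array_log_sd < 0 or self.spot_log_sd < 0:
            raise ValueError("noise sds must be non-negative")
        for p in self.artifact_rates.values():
            if not 0 <= p <= 1:
                raise ValueError("artifact rates must lie in [0, 1]")
        if self.spot_count < 1:
            raise ValueError("spot_count must be >= 1")

    def gene_sd(self, gene) -> float:
        if isinstance(self.gene_log_sd, dict):
            return float(self.gene_log_sd[gene])
        return float(self.gene_log_sd)
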