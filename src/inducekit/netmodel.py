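"""Per-gene sparse dynamical regression across induction experiments.

Each target gene i is modeled point-wise on finite-difference intervals:

    d ln(y_ijt) / dt  ~=  sum_k alpha_ik (y_kjt - 1)
                          + beta_ik (y_ijt * y_kjt - 1) / y_ijt

with predictors evaluated at the interval start. Because every timecourse
is normalized to y = 1 at t = 0, all predictors vanish on the first
interval's left endpoint, so the predicted rate at induction time is
structurally zero (the pre-induction steady-state constraint); accordingly
no intercept is ever fit. L1 regularization (LASSO) shrinks uninformative
coefficients to exactly zero; the per-target penalty is chosen by BIC by
default, with leave-one-experiment-out cross-validation available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

from .containers import EXP, GENE, TIME, ExpressionCube

DEFAULT_LAMBDA_GRID = tuple(np.geomspace(1e-6, 30.0, 30))


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Finite-difference regression rows for the dynamical model.

    Rows are indexed by (experiment, interval); the dependent variable and
    the target-specific beta terms are materialized per target via
    :meth:`for_target`. ``alpha_terms[k]`` holds ``y_k - 1`` at interval
    starts, shared by every target.
    """

    cube: ExpressionCube
    targets: list
    regulators: list
    self_edges: bool = False
    predictor_point: str = "start"  # or "midpoint"
    space: str = "log"  # or "linear"
    use_beta: bool = True
    dependent_map: dict | None = None  # negative control: exp -> exp for the dependent
    induced_map: dict | None = None  # exp -> induced gene; drops exogenous rows
    meta: pd.DataFrame = field(init=False)
    _y_start: pd.DataFrame = field(init=False, repr=False)
    _dep: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self):
        rows = []
        y_start_cols = {}
        dep_cols = {}
        for exp_id in self.cube.experiments:
            times = self.cube.times(exp_id)
            mat = self.cube.exp_matrix(exp_id).to_numpy(dtype=float)
            logm = np.log(mat)
            for m in range(len(times) - 1):
                dt = times[m + 1] - times[m]
                key = (exp_id, m)
                rows.append(
                    {EXP: exp_id, "interval": m, "t_start": times[m],
                     "t_end": times[m + 1], "dt": dt}
                )
                if self.predictor_point == "midpoint":
                    y_pred = 0.5 * (mat[:, m] + mat[:, m + 1])
                else:
                    y_pred = mat[:, m]
                y_start_cols[key] = y_pred
                if self.space == "log":
                    dep_cols[key] = (logm[:, m + 1] - logm[:, m]) / dt
                else:
                    dep_cols[key] = (mat[:, m + 1] - mat[:, m]) / dt
        self.meta = pd.DataFrame(rows)
        idx = pd.MultiIndex.from_frame(self.meta[[EXP, "interval"]])
        genes = self.cube.genes
        self._y_start = pd.DataFrame(
            np.column_stack([y_start_cols[k] for k in idx]), index=genes, columns=idx
        )
        if self.dependent_map:
            # re-source each row's dependent variable from the mapped
            # experiment (requires identical grids)
            dep_cols = {(e, m): dep_cols[(self.dependent_map.get(e, e), m)] for e, m in idx}
        self._dep = pd.DataFrame(
            np.column_stack([dep_cols[k] for k in idx]), index=genes, columns=idx
        )

    @property
    def n_rows(self) -> int:
        return len(self.meta)

    def regulators_for(self, target) -> list:
        if self.self_edges:
            return list(self.regulators)
        return [r for r in self.regulators if r != target]

    def target_row_mask(self, target) -> np.ndarray:
        """Rows used for one target's regression.

        When ``induced_map`` is set, rows of the experiment in which the
        target itself is induced are dropped: there its dynamics are forced
        by the inducer (exogenous), not by the network, and would otherwise
        contaminate the fit with unexplainable variance."""
        mask = np.ones(self.n_rows, dtype=bool)
        if self.induced_map:
            own = {e for e, g in self.induced_map.items() if g == target}
            if own:
                mask &= ~self.meta[EXP].isin(own).to_numpy()
        return mask

    def for_target(self, target, masked: bool = True) -> tuple[np.ndarray, np.ndarray, list]:
        """(X, y, column names) for one target's regression.

        Columns come in pairs ``alpha:<reg>``/``beta:<reg>`` (or alpha only
        when interaction terms are off). No intercept column exists.
        ``masked=False`` returns every row (used when evaluating the fitted
        model rather than estimating it).
        """
        regs = self.regulators_for(target)
        ys = self._y_start
        y_i = ys.loc[target].to_numpy()
        cols, names = [], []
        for reg in regs:
            y_k = ys.loc[reg].to_numpy()
            cols.append(y_k - 1.0)
            names.append(f"alpha:{reg}")
            if self.use_beta:
                cols.append((y_i * y_k - 1.0) / y_i)
                names.append(f"beta:{reg}")
        X = np.column_stack(cols) if cols else np.empty((self.n_rows, 0))
        y = self._dep.loc[target].to_numpy()
        if masked:
            mask = self.target_row_mask(target)
            X, y = X[mask], y[mask]
        return X, y, names

    def rows_for_experiments(self, experiments) -> np.ndarray:
        return self.meta[EXP].isin(set(experiments)).to_numpy()


def build_design(
    cube: ExpressionCube,
    targets: list | None = None,
    regulators: list | None = None,
    self_edges: bool = False,
    predictor_point: str = "start",
    space: str = "log",
    use_beta: bool = True,
    dependent_map: dict | None = None,
    induced_map: dict | None = None,
) -> DesignMatrix:
    """Assemble the finite-difference design for the given cube."""
    return DesignMatrix(
        cube=cube,
        targets=list(targets) if targets is not None else list(cube.genes),
        regulators=list(regulators) if regulators is not None else list(cube.genes),
        self_edges=self_edges,
        predictor_point=predictor_point,
        space=space,
        use_beta=use_beta,
        dependent_map=dependent_map,
        induced_map=induced_map,
    )


# --------------------------------------------------------------------------
# penalized fitting
# --------------------------------------------------------------------------

def lasso_objective(X: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float) -> float:
    """The optimized objective: ||y - Xw||^2 + lam * ||w||_1."""
    resid = y - X @ w
    return float(resid @ resid + lam * np.abs(w).sum())


def fit_lasso(X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-8) -> np.ndarray:
    """Minimize ``||y - Xw||^2 + lam * ||w||_1`` with no intercept.

    All-zero predictor columns are dropped internally and reported as zero
    coefficients. ``lam = 0`` falls back to least squares. ``tol`` is the
    coordinate-descent duality-gap tolerance (relative to ||y||^2).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    n, p = X.shape
    if p == 0:
        return np.empty(0)
    keep = np.flatnonzero(np.any(X != 0, axis=0))
    w = np.zeros(p)
    if keep.size == 0:
        return w
    Xk = X[:, keep]
    if lam == 0:
        w[keep] = np.linalg.lstsq(Xk, y, rcond=None)[0]
        return w
    # sklearn minimizes 1/(2n) ||y - Xw||^2 + a ||w||_1
    model = Lasso(alpha=lam / (2.0 * n), fit_intercept=False, max_iter=50_000, tol=tol)
    model.fit(Xk, y)
    w[keep] = model.coef_
    return w


def fit_gene_lasso(design: DesignMatrix, target, lam: float) -> pd.Series:
    """Fit one target's regression at a fixed penalty; returns coefficients
    indexed by term name (``alpha:<reg>`` / ``beta:<reg>``)."""
    X, y, names = design.for_target(target)
    return pd.Series(fit_lasso(X, y, lam), index=names, name=target)


def _coef_path(X: np.ndarray, y: np.ndarray, lams: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Warm-started coefficients for a whole penalty grid.

    Returns an array of shape (len(lams), p) matching the objective of
    :func:`fit_lasso` at each lambda (no intercept)."""
    n, p = X.shape
    keep = np.flatnonzero(np.any(X != 0, axis=0))
    out = np.zeros((len(lams), p))
    if keep.size == 0:
        return out
    order = np.argsort(lams)[::-1]  # lasso_path expects descending alphas
    alphas = np.asarray(lams, dtype=float)[order] / (2.0 * n)
    _, coefs, _ = lasso_path(X[:, keep], y, alphas=alphas, tol=tol, max_iter=50_000)
    out[order[:, None], keep[None, :]] = coefs.T
    return out


def cross_validate(
    design: DesignMatrix,
    target,
    lam_grid=DEFAULT_LAMBDA_GRID,
    one_se: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Leave-one-experiment-out CV over a penalty grid.

    Returns the selected lambda and a table of per-lambda mean held-out MSE
    (plus its standard error across folds). Selection is min-MSE, or the
    sparsest lambda within one SE of the minimum when ``one_se``.
    """
    experiments = self_exps = design.cube.experiments
    if len(experiments) < 3:
        raise ValueError("leave-one-experiment-out CV needs >= 3 experiments")
    X, y, _ = design.for_target(target)
    lam_grid = np.asarray(sorted(lam_grid))
    row_exps = design.meta[EXP].to_numpy()[design.target_row_mask(target)]
    fold_mse = np.empty((len(lam_grid), len(self_exps)))
    for j, held in enumerate(experiments):
        test = row_exps == held
        if not test.any() or test.all():
            fold_mse[:, j] = np.nan
            continue
        train = ~test
        W = _coef_path(X[train], y[train], lam_grid)
        for a in range(len(lam_grid)):
            resid = y[test] - X[test] @ W[a]
            fold_mse[a, j] = float(resid @ resid) / test.sum()
    mean_mse = np.nanmean(fold_mse, axis=1)
    n_folds = np.sum(~np.isnan(fold_mse[0]))
    se_mse = np.nanstd(fold_mse, axis=1, ddof=1) / np.sqrt(max(n_folds, 1))
    best = int(np.argmin(mean_mse))
    if one_se:
        ok = np.flatnonzero(mean_mse <= mean_mse[best] + se_mse[best])
        best = int(ok.max())  # largest lambda (sparsest) within one SE
    table = pd.DataFrame({"lambda": lam_grid, "mse": mean_mse, "se": se_mse})
    return float(lam_grid[best]), table


def select_lambda_bic(
    design: DesignMatrix, target, lam_grid=DEFAULT_LAMBDA_GRID
) -> tuple[float, pd.DataFrame]:
    """Pick the penalty minimizing BIC = n ln(RSS/n) + df ln(n), df = number
    of nonzero coefficients. Ties resolve to the largest lambda (sparsest)."""
    X, y, _ = design.for_target(target)
    n = y.size
    lam_grid = np.asarray(sorted(lam_grid))
    W = _coef_path(X, y, lam_grid)
    recs = []
    for lam, w in zip(lam_grid, W):
        resid = y - X @ w
        rss = max(float(resid @ resid), 1e-300)
        df = int(np.count_nonzero(w))
        recs.append({"lambda": lam, "rss": rss, "df": df,
                     "bic": n * np.log(rss / n) + df * np.log(n)})
    table = pd.DataFrame(recs)
    # iterate descending lambda; strict improvement required to move off the
    # sparser (larger-lambda) candidate
    best_lam, best_bic = None, np.inf
    for _, row in table.iloc[::-1].iterrows():
        if row["bic"] < best_bic - 1e-12:
            best_lam, best_bic = row["lambda"], row["bic"]
    return float(best_lam), table


# --------------------------------------------------------------------------
# whole-network fitting
# --------------------------------------------------------------------------

@dataclass
class NetworkModel:
    """Fitted per-target coefficient vectors plus diagnostics."""

    genes: list
    regulators: list
    alpha: pd.DataFrame  # target x regulator
    beta: pd.DataFrame
    lambdas: pd.Series
    diagnostics: pd.DataFrame
    config: dict

    def edge_scores(self) -> pd.DataFrame:
        """Candidate edges ranked by |alpha| + |beta| (descending)."""
        rows = []
        for target in self.alpha.index:
            for reg in self.alpha.columns:
                if reg == target and not self.config.get("self_edges", False):
                    continue
                score = abs(self.alpha.loc[target, reg]) + abs(self.beta.loc[target, reg])
                rows.append({"target": target, "regulator": reg, "score": score})
        return (
            pd.DataFrame(rows)
            .sort_values(["score", "target", "regulator"], ascending=[False, True, True])
            .reset_index(drop=True)
        )

    def coefficients_frame(self) -> pd.DataFrame:
        rows = []
        for target in self.alpha.index:
            for reg in self.alpha.columns:
                a, b = self.alpha.loc[target, reg], self.beta.loc[target, reg]
                if a != 0 or b != 0:
                    rows.append({"target": target, "regulator": reg, "alpha": a,
                                 "beta": b, "lambda": self.lambdas[target]})
        return pd.DataFrame(rows, columns=["target", "regulator", "alpha", "beta", "lambda"])

    @classmethod
    def from_coefficients(cls, frame: pd.DataFrame, genes: list,
                          config: dict | None = None) -> "NetworkModel":
        """Rebuild a model from a sparse coefficients table (target,
        regulator, alpha, beta[, lambda])."""
        genes = list(genes)
        alpha = pd.DataFrame(0.0, index=genes, columns=genes)
        beta = pd.DataFrame(0.0, index=genes, columns=genes)
        lambdas = pd.Series(np.nan, index=genes, dtype=float)
        has_lambda = "lambda" in frame.columns
        for _, row in frame.iterrows():
            alpha.loc[row["target"], row["regulator"]] = row["alpha"]
            beta.loc[row["target"], row["regulator"]] = row["beta"]
            if has_lambda:
                lambdas[row["target"]] = row["lambda"]
        return cls(genes=genes, regulators=genes, alpha=alpha, beta=beta,
                   lambdas=lambdas, diagnostics=pd.DataFrame(index=genes),
                   config=config or {"self_edges": False})


def fit_network(
    cube: ExpressionCube,
    targets: list | None = None,
    regulators: list | None = None,
    lam_grid=DEFAULT_LAMBDA_GRID,
    lambda_rule: str = "bic",  # "bic" | "cv" | "fixed"
    fixed_lambda: float | None = None,
    use_beta: bool = True,
    space: str = "log",
    self_edges: bool = False,
    predictor_point: str = "start",
    dependent_map: dict | None = None,
    induced_map: dict | None = None,
) -> NetworkModel:
    """Fit the sparse dynamical regression for every target gene.

    Per-target failures are isolated: a gene whose fit raises is recorded
    with NaN diagnostics and zero coefficients, and the loop continues.
    ``dependent_map`` mismatches dependent and predictor experiments as a
    negative control (see :func:`permute_experiment_labels`);
    ``induced_map`` (experiment -> induced gene) excludes each induced
    gene's exogenous rows from its own regression.
    """
    design = build_design(
        cube, targets, regulators, self_edges, predictor_point, space, use_beta,
        dependent_map, induced_map,
    )
    targets = design.targets
    regulators = design.regulators
    alpha = pd.DataFrame(0.0, index=targets, columns=regulators)
    beta = pd.DataFrame(0.0, index=targets, columns=regulators)
    lambdas = pd.Series(np.nan, index=targets, dtype=float)
    diags = []
    for target in targets:
        try:
            if lambda_rule == "bic":
                lam, _ = select_lambda_bic(design, target, lam_grid)
            elif lambda_rule == "cv":
                lam, _ = cross_validate(design, target, lam_grid)
            elif lambda_rule == "fixed":
                if fixed_lambda is None:
                    raise ValueError("fixed_lambda required with lambda_rule='fixed'")
                lam = float(fixed_lambda)
            else:
                raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
            coefs = fit_gene_lasso(design, target, lam)
            X, y, names = design.for_target(target)
            pred = X @ coefs.to_numpy()
            ss_res = float(np.sum((y - pred) ** 2))
            ss_tot = float(np.sum(y**2))  # no-intercept R^2 against the zero model
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
            for name, value in coefs.items():
                kind, reg = name.split(":", 1)
                (alpha if kind == "alpha" else beta).loc[target, reg] = value
            lambdas[target] = lam
            diags.append({"target": target, "lambda": lam, "r2_insample": r2,
                          "n_rows": y.size, "n_nonzero": int(np.count_nonzero(coefs)),
                          "error": None})
        except Exception as exc:  # pragma: no cover - defensive isolation
            diags.append({"target": target, "lambda": np.nan, "r2_insample": np.nan,
                          "n_rows": 0, "n_nonzero": 0, "error": str(exc)})
    return NetworkModel(
        genes=list(cube.genes),
        regulators=regulators,
        alpha=alpha,
        beta=beta,
        lambdas=lambdas,
        diagnostics=pd.DataFrame(diags).set_index("target"),
        config={
            "lambda_rule": lambda_rule,
            "use_beta": use_beta,
            "space": space,
            "self_edges": self_edges,
            "predictor_point": predictor_point,
            "induced_map": induced_map,
        },
    )


def predicted_rates(model: NetworkModel, cube: ExpressionCube, target) -> pd.Series:
    """Model-predicted d ln y/dt per (experiment, interval) for one target."""
    design = build_design(
        cube,
        targets=[target],
        regulators=model.regulators,
        self_edges=model.config.get("self_edges", False),
        predictor_point=model.config.get("predictor_point", "start"),
        space=model.config.get("space", "log"),
        use_beta=model.config.get("use_beta", True),
    )
    X, _, names = design.for_target(target, masked=False)
    w = np.array(
        [
            (model.alpha if n.startswith("alpha:") else model.beta).loc[target, n.split(":", 1)[1]]
            for n in names
        ]
    )
    idx = pd.MultiIndex.from_frame(design.meta[[EXP, "interval"]])
    return pd.Series(X @ w, index=idx, name=target)


def integrate_predictions(model: NetworkModel, cube: ExpressionCube) -> ExpressionCube:
    """Teacher-forced integration of fitted rates into predicted trajectories.

    Predicted ``ln y`` at each grid time is the cumulative sum of the fitted
    rate times the interval width, starting at 0 (so predictions share the
    steady-state anchor y = 1 at t = 0). Predictors are the *observed*
    values, mirroring the point-wise regression.
    """
    values = {}
    targets = list(model.alpha.index)
    for target in targets:
        rates = predicted_rates(model, cube, target)
        for exp_id in cube.experiments:
            times = cube.times(exp_id)
            r = rates.loc[exp_id].to_numpy()
            dt = np.diff(times)
            ln_y = np.concatenate([[0.0], np.cumsum(r * dt)])
            for t, v in zip(times, np.exp(ln_y)):
                values.setdefault((exp_id, t), {})[target] = v
    cols = pd.MultiIndex.from_tuples(sorted(values), names=[EXP, TIME])
    mat = pd.DataFrame(
        {c: pd.Series(values[c]) for c in sorted(values)}, index=pd.Index(targets, name=GENE)
    )
    mat.columns = cols
    return ExpressionCube(mat)


def permute_experiment_labels(
    experiments: list, induced_map: dict | None = None, seed: int = 0
) -> dict:
    """Negative-control permutation of the dependent variable's experiments.

    Returns a mapping exp -> exp under which each target's rate of change is
    read from a *different* experiment than its predictors, destroying the
    regulator/target coupling. When ``induced_map`` (exp -> induced gene) is
    given, the permutation additionally never maps an experiment onto one
    inducing the same gene -- repeat inductions of one regulator would
    otherwise silently re-align signal with predictors.
    """
    rng = np.random.default_rng(seed)
    exps = list(experiments)
    n = len(exps)
    if n < 2:
        return {e: e for e in exps}
    for _ in range(10_000):
        perm = rng.permutation(n)
        ok = all(
            perm[j] != j
            and (induced_map is None or induced_map[exps[perm[j]]] != induced_map[exps[j]])
            for j in range(n)
        )
        if ok:
            return {exps[j]: exps[perm[j]] for j in range(n)}
    raise RuntimeError("could not draw a valid label permutation")


def fit_baseline_lasso(
    cube: ExpressionCube,
    lam: float = 1e-2,
    regulators: list | None = None,
) -> pd.DataFrame:
    """Comparator model: expression-on-expression LASSO with a global lambda.

    Each gene's log2 expression across all (experiment, t > 0) samples is
    regressed on all other genes' log2 expression at the same samples (no
    dynamics, no steady-state structure). Returns the coefficient matrix as
    edge scores for benchmarking against the dynamical model.
    """
    log2 = np.log2(cube.values)
    post = log2.loc[:, log2.columns.get_level_values(1) > 0]
    genes = list(post.index)
    regulators = regulators or genes
    rows = []
    mat = post.to_numpy(dtype=float)
    g_index = {g: i for i, g in enumerate(genes)}
    for target in genes:
        regs = [r for r in regulators if r != target]
        X = mat[[g_index[r] for r in regs], :].T
        y = mat[g_index[target], :]
        w = fit_lasso(X, y, lam)
        for reg, coef in zip(regs, w):
            rows.append({"target": target, "regulator": reg, "score": abs(coef)})
    return pd.DataFrame(rows)
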