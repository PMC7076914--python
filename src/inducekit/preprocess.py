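"""Raw -> cleaned -> thresholded signal chain for two-color spot intensities.

Stages, in order:

1. :func:`aggregate_spots` -- per-spot ratios with an intensity floor,
   aggregated to per-observation min/max/median/sd;
2. :func:`repair_spot_disagreement` -- observations whose spots disagree by
   more than 4x are replaced by the geometric mean of bracketing times;
3. :func:`repair_spike_outliers` -- a >= 4x move immediately reversed by a
   >= 4x opposite move is treated as a one-point artifact and likewise
   replaced;
4. :func:`repair_crosstalk` -- timecourses whose green channel inflates
   wholesale after t = 0 (red-into-green leakage) are recomputed against the
   time-zero green channel;
5. :func:`normalize_to_t0` -- ratios divided by the t = 0 ratio so every
   timecourse starts at exactly 1;
6. :func:`subtract_class_median` -- the per-gene median log timecourse of
   each induction-system class (GEV/ZEV) is removed, cancelling the shared
   mild stress signature;
7. :func:`threshold_noise` -- timecourses statistically consistent with a
   two-component (gene + array) log-normal noise model are set to exactly
   zero log fold change (hard thresholding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import EXP, GENE, TIME, ExpressionCube

#: Intensity floor applied to both channels before forming ratios (a.u.).
FLOOR_C = 2.0

MAD_SCALE = 1.4826  # normal-consistency factor for median absolute deviation


def spot_ratio(red, green, C: float = FLOOR_C):
    """Per-spot expression ratio ``max(red, C) / max(green, C)``."""
    if C <= 0:
        raise ValueError("floor constant C must be positive")
    return np.maximum(np.asarray(red, dtype=float), C) / np.maximum(
        np.asarray(green, dtype=float), C
    )


def aggregate_spots(spots: pd.DataFrame, C: float = FLOOR_C) -> pd.DataFrame:
    """Aggregate spot-level intensities to per-observation ratio statistics.

    Returns one row per (gene, experiment, time) with columns ``ratio_min``,
    ``ratio_max``, ``ratio_median``, ``ratio_sd`` and ``n_spots``. For the
    usual two spots, the sd equals ``(max - min)/sqrt(2)``.
    """
    spots = spots.copy()
    spots["ratio"] = spot_ratio(spots["red"], spots["green"], C)
    grouped = spots.groupby([GENE, EXP, TIME])["ratio"]
    agg = grouped.agg(
        ratio_min="min", ratio_max="max", ratio_median="median", ratio_sd=lambda s: s.std(ddof=1), n_spots="count"
    )
    agg["ratio_sd"] = agg["ratio_sd"].fillna(0.0)
    return agg.reset_index()


def _geometric_repair(values: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    """Replace flagged entries by the geometric mean of the nearest
    non-flagged bracketing values (single neighbor at the ends)."""
    out = values.copy()
    ok = ~flagged
    idx_ok = np.flatnonzero(ok)
    if idx_ok.size == 0:
        return out  # nothing to anchor a repair on
    for i in np.flatnonzero(flagged):
        left = idx_ok[idx_ok < i]
        right = idx_ok[idx_ok > i]
        if left.size and right.size:
            out[i] = np.sqrt(values[left[-1]] * values[right[0]])
        elif left.size:
            out[i] = values[left[-1]]
        else:
            out[i] = values[right[0]]
    return out


def repair_spot_disagreement(
    agg: pd.DataFrame, threshold: float = 4.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repair observations whose duplicate spots disagree by > ``threshold``.

    Disagreement is judged symmetrically as ``ratio_max / ratio_min`` of the
    per-spot ratios. Flagged observations have their median ratio replaced
    by the geometric mean of the nearest non-flagged bracketing time points
    (or the single neighbor at the ends). Timecourses of length < 2 are
    flagged but cannot be repaired.
    """
    agg = agg.sort_values([GENE, EXP, TIME]).reset_index(drop=True)
    repaired = agg["ratio_median"].to_numpy(dtype=float).copy()
    disagree = (agg["ratio_max"] / agg["ratio_min"]).to_numpy() > threshold
    flags = []
    for (g, e), sub in agg.groupby([GENE, EXP], sort=False):
        idx = sub.index.to_numpy()
        mask = disagree[idx]
        if not mask.any():
            continue
        if idx.size >= 2:
            repaired[idx] = _geometric_repair(repaired[idx], mask)
        for i in idx[mask]:
            flags.append({GENE: g, EXP: e, TIME: agg.loc[i, TIME], "repairable": idx.size >= 2})
    out = agg.copy()
    out["ratio_median"] = repaired
    return out, pd.DataFrame(flags, columns=[GENE, EXP, TIME, "repairable"])


def repair_spike_outliers(
    agg: pd.DataFrame, threshold: float = 4.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repair one-point spikes: a >= ``threshold`` move between consecutive
    times followed by a >= ``threshold`` move in the opposite direction.

    Both up-then-down and down-then-up excursions qualify. The central point
    is replaced by the geometric mean of its bracketing (non-flagged)
    neighbors.
    """
    agg = agg.sort_values([GENE, EXP, TIME]).reset_index(drop=True)
    repaired = agg["ratio_median"].to_numpy(dtype=float).copy()
    flags = []
    for (g, e), sub in agg.groupby([GENE, EXP], sort=False):
        idx = sub.index.to_numpy()
        v = repaired[idx]
        if idx.size < 3:
            continue
        mask = np.zeros(idx.size, dtype=bool)
        up = v[1:] / v[:-1]
        for m in range(1, idx.size - 1):
            rise, fall = up[m - 1], up[m]
            if (rise >= threshold and 1.0 / fall >= threshold) or (
                1.0 / rise >= threshold and fall >= threshold
            ):
                mask[m] = True
        if not mask.any():
            continue
        repaired[idx] = _geometric_repair(v, mask)
        for i in idx[mask]:
            flags.append({GENE: g, EXP: e, TIME: agg.loc[i, TIME]})
    out = agg.copy()
    out["ratio_median"] = repaired
    return out, pd.DataFrame(flags, columns=[GENE, EXP, TIME])


def repair_crosstalk(
    agg: pd.DataFrame,
    spots: pd.DataFrame,
    C: float = FLOOR_C,
    quantile: float = 0.3,
    green_factor: float = 8.0,
    log2_change: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repair timecourses whose green channel inflates after t = 0.

    Detection (both criteria must hold, a conjunction):

    - the 30% quantile over t > 0 of ``green(t)/green(0)`` exceeds
      ``green_factor`` (default 8), and
    - the 30% quantile over t > 0 of ``|log2(ratio(t)/ratio(0))|`` exceeds
      ``log2_change`` (default a twofold change).

    Repair recomputes every spot ratio using that spot's t = 0 green channel
    (with the same intensity floor) and re-aggregates the medians.
    """
    agg = agg.sort_values([GENE, EXP, TIME]).reset_index(drop=True)
    green_med = (
        spots.groupby([GENE, EXP, TIME])["green"].median().rename("green_median")
    )
    out = agg.copy()
    flags = []
    for (g, e), sub in agg.groupby([GENE, EXP], sort=False):
        sub = sub.sort_values(TIME)
        times = sub[TIME].to_numpy(dtype=float)
        if times.size < 2 or times[0] != 0:
            continue
        gm = green_med.loc[g, e].sort_index()
        green_ratio = gm.loc[gm.index > 0].to_numpy() / gm.loc[0.0]
        ratio = sub["ratio_median"].to_numpy(dtype=float)
        log2_dev = np.abs(np.log2(ratio[1:] / ratio[0]))
        if not (
            np.quantile(green_ratio, quantile) > green_factor
            and np.quantile(log2_dev, quantile) > log2_change
        ):
            continue
        # repair: duplicate each spot's time-zero green across the timecourse
        course_spots = spots[(spots[GENE] == g) & (spots[EXP] == e)]
        g0 = course_spots[course_spots[TIME] == 0].set_index("spot_index")["green"]
        fixed = course_spots.copy()
        fixed["green0"] = fixed["spot_index"].map(g0).fillna(g0.median())
        fixed["ratio"] = spot_ratio(fixed["red"], fixed["green0"], C)
        med = fixed.groupby(TIME)["ratio"].median()
        out.loc[sub.index, "ratio_median"] = med.loc[sub[TIME]].to_numpy()
        for t in times:
            flags.append({GENE: g, EXP: e, TIME: t})
    return out, pd.DataFrame(flags, columns=[GENE, EXP, TIME])


def normalize_to_t0(agg: pd.DataFrame) -> ExpressionCube:
    """Divide each timecourse's median ratio by its t = 0 value (y_0 = 1)."""
    wide = agg.pivot_table(index=GENE, columns=[EXP, TIME], values="ratio_median", sort=True)
    if wide.isna().any().any():
        raise ValueError("missing observations: incomplete gene x (experiment, time) grid")
    for exp_id in wide.columns.get_level_values(0).unique():
        block = wide[exp_id]
        if 0.0 not in block.columns:
            raise ValueError(f"experiment {exp_id!r} lacks a t = 0 sample")
        wide[exp_id] = block.div(block[0.0], axis=0).to_numpy()
    return ExpressionCube(wide)


def subtract_class_median(
    cube: ExpressionCube, class_map: dict
) -> tuple[ExpressionCube, list]:
    """Remove each class's per-gene median log timecourse.

    For every gene and system class (GEV/ZEV), the median of ``ln y`` across
    that class's experiments is computed per time point and subtracted from
    every experiment of the class. A gene not regulated by most induced TFs
    has a median reflecting only shared background (the mild stress
    signature), which this cancels. Classes with a single experiment are
    skipped with a warning entry (subtraction would zero them out).
    """
    log_vals = np.log(cube.values)
    classes: dict[str, list] = {}
    for exp_id in cube.experiments:
        classes.setdefault(class_map[exp_id], []).append(exp_id)
    skipped = []
    for cls, exps in classes.items():
        if len(exps) < 2:
            skipped.append(cls)
            continue
        # median over experiments of the class, per gene and time
        block = pd.concat([log_vals[e] for e in exps], axis=1, keys=exps)
        med = block.T.groupby(level=1).median().T  # gene x time
        for e in exps:
            log_vals[e] = (log_vals[e] - med).to_numpy()
    out = ExpressionCube(np.exp(log_vals))
    out.flags = dict(cube.flags)
    return out, skipped


@dataclass
class NoiseThresholdResult:
    cube: ExpressionCube
    selected: pd.DataFrame  # per (gene, experiment): statistic, pvalue, qvalue, selected
    selected_fraction: float
    sigma: pd.DataFrame = field(repr=False, default=None)  # per-observation sd estimates


def threshold_noise(
    cube: ExpressionCube,
    fdr_q: float = 0.05,
    sd_floor: float = 1e-3,
) -> NoiseThresholdResult:
    """Hard-threshold timecourses that are consistent with measurement noise.

    Noise model: the log value of an invariant gene is
    ``N(0, sigma_gene_i^2 + sigma_array_a^2)`` with one array per
    (experiment, time) sample. Components are estimated robustly from the
    invariant majority via MAD: with per-gene scale ``s_i`` (over arrays),
    per-array scale ``s_a`` (over genes) and overall scale ``s``, the
    moment-matched per-observation variance is
    ``sigma_ia^2 = max(s_i^2 + s_a^2 - s^2, sd_floor^2)``.

    Each timecourse is scored by ``T = sum_{t>0} (l_t / sigma_it)^2``,
    compared to chi-square with one degree of freedom per post-zero time;
    Benjamini-Hochberg selects signal at ``fdr_q``. Non-selected timecourses
    are set to exactly zero log fold change.
    """
    log_vals = np.log(cube.values)
    post = log_vals.loc[:, log_vals.columns.get_level_values(1) > 0]

    arr = post.to_numpy(dtype=float)
    s_gene = MAD_SCALE * np.median(np.abs(arr), axis=1)  # per gene, over arrays
    s_array = MAD_SCALE * np.median(np.abs(arr), axis=0)  # per array, over genes
    s_all = MAD_SCALE * np.median(np.abs(arr))
    var = s_gene[:, None] ** 2 + s_array[None, :] ** 2 - s_all**2
    var = np.maximum(var, sd_floor**2)

    frames = []
    values = cube.values.copy()
    sigma = pd.DataFrame(np.sqrt(var), index=post.index, columns=post.columns)
    for exp_id in cube.experiments:
        sub = post[exp_id]
        stat = ((sub / sigma[exp_id]) ** 2).sum(axis=1)
        pvals = stats.chi2.sf(stat, sub.shape[1])
        frames.append(
            pd.DataFrame({GENE: sub.index, EXP: exp_id, "statistic": stat.to_numpy(),
                          "pvalue": pvals})
        )
    table = pd.concat(frames, ignore_index=True)
    reject, qvals, _, _ = multipletests(table["pvalue"], alpha=fdr_q, method="fdr_bh")
    table["qvalue"] = qvals
    table["selected"] = reject

    invariant = pd.DataFrame(False, index=values.index, columns=values.columns)
    for exp_id, sub in table.groupby(EXP):
        zeroed = sub.loc[~sub["selected"], GENE]
        cols = [(exp_id, t) for t in cube.times(exp_id)]
        values.loc[zeroed, cols] = 1.0  # exactly zero log fold change
        invariant.loc[zeroed, cols] = True
    out = ExpressionCube(values)
    out.flags = dict(cube.flags)
    out.flags["invariant"] = invariant
    return NoiseThresholdResult(
        cube=out,
        selected=table,
        selected_fraction=float(table["selected"].mean()),
        sigma=sigma,
    )


@dataclass
class CleanResult:
    cube: ExpressionCube              # cleaned, class-median-subtracted, thresholded
    cleaned_cube: ExpressionCube      # before thresholding
    disagreement_flags: pd.DataFrame
    spike_flags: pd.DataFrame
    crosstalk_flags: pd.DataFrame
    threshold: NoiseThresholdResult | None
    report: dict


def clean_pipeline(
    spots: pd.DataFrame,
    class_map: dict,
    C: float = FLOOR_C,
    fdr_q: float = 0.05,
    apply_threshold: bool = True,
) -> CleanResult:
    """Run the full raw -> cleaned -> thresholded chain on a spot table."""
    agg = aggregate_spots(spots, C)
    agg, dis_flags = repair_spot_disagreement(agg)
    agg, spike_flags = repair_spike_outliers(agg)
    agg, cross_flags = repair_crosstalk(agg, spots, C)
    cube = normalize_to_t0(agg)
    cube, skipped = subtract_class_median(cube, class_map)
    cleaned = cube.copy()
    thr = threshold_noise(cube, fdr_q) if apply_threshold else None
    report = {
        "n_spot_disagreement_repairs": int(len(dis_flags)),
        "n_spike_repairs": int(len(spike_flags)),
        "n_crosstalk_timecourses": int(cross_flags[[GENE, EXP]].drop_duplicates().shape[0])
        if len(cross_flags)
        else 0,
        "classes_skipped_in_median_subtraction": skipped,
        "selected_fraction": thr.selected_fraction if thr else None,
    }
    return CleanResult(
        cube=thr.cube if thr else cube,
        cleaned_cube=cleaned,
        disagreement_flags=dis_flags,
        spike_flags=spike_flags,
        crosstalk_flags=cross_flags,
        threshold=thr,
        report=report,
    )
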