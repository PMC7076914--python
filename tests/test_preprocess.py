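"""Cleaning chain: spot aggregation, outlier/crosstalk repair, class medians,
noise-model hard thresholding."""

import numpy as np
import pandas as pd
import pytest

import inducekit as ik
from inducekit.preprocess import (
    aggregate_spots,
    normalize_to_t0,
    repair_crosstalk,
    repair_spike_outliers,
    repair_spot_disagreement,
    spot_ratio,
)

from conftest import GRID, make_cube


def spots_from_medians(medians, gene="g", exp="e", times=None, split=1.0):
    """Two-spot table whose spot ratios are median*split and median/split."""
    times = times if times is not None else GRID[: len(medians)]
    rows = []
    for t, m in zip(times, medians):
        for spot, fac in enumerate((split, 1.0 / split)):
            rows.append({"gene": gene, "experiment": exp, "time_min": float(t),
                         "spot_index": spot, "red": 1000.0 * m * fac, "green": 1000.0})
    return pd.DataFrame(rows)


class TestAggregation:
    @pytest.mark.parametrize(
        "red,green,expected",
        [(8, 2, 4.0), (0, 0, 1.0), (200, 100, 2.0), (1, 4, 0.5)],
    )
    def test_floored_ratio(self, red, green, expected):
        assert spot_ratio(red, green, C=2.0) == expected

    def test_two_spot_stats(self):
        spots = spots_from_medians([2.0], split=1.0)
        agg = aggregate_spots(spots)
        assert agg.ratio_median[0] == 2.0 and agg.ratio_sd[0] == 0.0

    def test_two_spot_sd_is_range_over_sqrt2(self):
        spots = spots_from_medians([2.0], split=2.0)  # ratios 4 and 1
        agg = aggregate_spots(spots)
        assert agg.ratio_sd[0] == pytest.approx((4 - 1) / np.sqrt(2))
        assert agg.ratio_median[0] == pytest.approx(2.5)


class TestSpotDisagreementRepair:
    def test_disagreeing_spots_replaced_by_bracketing_geometric_mean(self):
        spots = pd.concat([
            spots_from_medians([2.0], times=[0.0]),
            spots_from_medians([np.sqrt(20.0)], times=[5.0], split=np.sqrt(5.0)),
            spots_from_medians([8.0], times=[10.0]),
        ])
        agg = aggregate_spots(spots)
        out, flags = repair_spot_disagreement(agg)
        assert list(flags.time_min) == [5.0]
        assert out.sort_values("time_min").ratio_median.tolist()[1] == pytest.approx(4.0)

    def test_threefold_disagreement_untouched(self):
        spots = spots_from_medians([2.0, 2.0, 2.0], split=np.sqrt(3.0))
        agg = aggregate_spots(spots)
        out, flags = repair_spot_disagreement(agg)
        assert flags.empty
        assert np.array_equal(out.ratio_median, agg.ratio_median)

    def test_repair_is_idempotent(self, artifact_sim):
        agg = aggregate_spots(artifact_sim["spots"])
        once, _ = repair_spot_disagreement(agg)
        twice, _ = repair_spot_disagreement(once)
        assert np.array_equal(once.ratio_median, twice.ratio_median)


class TestSpikeRepair:
    @pytest.mark.parametrize(
        "medians,expected",
        [
            ([1, 4.5, 1], [1, 1, 1]),          # up then down, >= 4x both ways
            ([4, 1, 4], [4, 4, 4]),            # down then up
            ([1, 4, 16], [1, 4, 16]),          # monotone: no reversal
            ([1, 2, 1], [1, 2, 1]),            # below threshold
        ],
    )
    def test_spike_rule(self, medians, expected):
        agg = aggregate_spots(spots_from_medians(medians))
        out, _ = repair_spike_outliers(agg)
        assert out.sort_values("time_min").ratio_median.tolist() == pytest.approx(expected)

    def test_repaired_value_is_geometric_mean(self):
        agg = aggregate_spots(spots_from_medians([2.0, 32.0, 8.0]))
        out, flags = repair_spike_outliers(agg)
        assert list(flags.time_min) == [5.0]
        assert out.sort_values("time_min").ratio_median.tolist()[1] == pytest.approx(4.0)


class TestCrosstalkRepair:
    def _course(self, green_factor=10.0, red_factor=1.0):
        rows = []
        for t in GRID:
            inflate = t > 0
            rows.append({"gene": "g", "experiment": "e", "time_min": float(t),
                         "spot_index": 0,
                         "red": 1000.0 * (red_factor if inflate else 1.0),
                         "green": 1000.0 * (green_factor if inflate else 1.0)})
        return pd.DataFrame(rows)

    def test_inflated_green_repaired_to_time_zero_channel(self):
        spots = self._course(green_factor=10.0)
        agg = aggregate_spots(spots)
        out, flags = repair_crosstalk(agg, spots)
        assert not flags.empty
        # repaired ratio = red(t) / green(0) = 1.0 at every time
        assert np.allclose(out.ratio_median, 1.0)

    def test_constant_green_untouched(self):
        spots = self._course(green_factor=1.0)
        agg = aggregate_spots(spots)
        out, flags = repair_crosstalk(agg, spots)
        assert flags.empty and np.array_equal(out.ratio_median, agg.ratio_median)

    def test_conjunction_required(self):
        # green inflated but red inflated alike: log-ratio quantile ~ 0
        spots = self._course(green_factor=10.0, red_factor=10.0)
        agg = aggregate_spots(spots)
        out, flags = repair_crosstalk(agg, spots)
        assert flags.empty and np.array_equal(out.ratio_median, agg.ratio_median)


class TestClassMedian:
    def test_identical_timecourses_zeroed(self):
        vals = np.tile(np.linspace(1, 2, len(GRID)), (3, 4, 1))
        cube = make_cube(vals, ["a", "b", "c"], [f"e{i}" for i in range(4)])
        out, skipped = ik.subtract_class_median(cube, {f"e{i}": "ZEV" for i in range(4)})
        assert not skipped
        assert np.allclose(np.log(out.values.to_numpy()), 0.0)

    def test_minority_responder_preserved(self):
        vals = np.ones((1, 11, len(GRID)))
        vals[0, 0, :] = np.linspace(1, 4, len(GRID))  # responds in 1 of 11
        cube = make_cube(vals, ["g"], [f"e{i:02d}" for i in range(11)])
        out, _ = ik.subtract_class_median(cube, {f"e{i:02d}": "ZEV" for i in range(11)})
        assert np.allclose(out.exp_matrix("e00").to_numpy(), vals[0, 0])

    def test_single_experiment_class_skipped(self):
        vals = np.tile(np.linspace(1, 2, len(GRID)), (2, 1, 1))
        cube = make_cube(vals, ["a", "b"], ["only"])
        out, skipped = ik.subtract_class_median(cube, {"only": "GEV"})
        assert skipped == ["GEV"]
        assert np.array_equal(out.values.to_numpy(), cube.values.to_numpy())

    def test_per_class_median_of_output_is_zero(self, artifact_sim):
        cube = artifact_sim["cube"]
        out, _ = ik.subtract_class_median(cube, artifact_sim["class_map"])
        lv = np.log(out.values)
        for cls in ("GEV", "ZEV"):
            exps = [e for e, c in artifact_sim["class_map"].items() if c == cls]
            med = pd.concat([lv[e] for e in exps], keys=exps).groupby(level=1).median()
            assert np.abs(med.to_numpy()).max() < 1e-12


class TestThresholding:
    def test_flat_timecourse_never_selected(self):
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(0, 0.1, size=(200, 4, len(GRID))))
        vals[:, :, 0] = 1.0
        vals[0] = 1.0  # exactly flat in all experiments
        cube = make_cube(vals, [f"g{i}" for i in range(200)], list("abcd"))
        res = ik.threshold_noise(cube)
        sel = res.selected.set_index("gene")["selected"]
        assert not sel.loc["g0"].any()

    def test_strong_signal_selected_and_preserved(self):
        rng = np.random.default_rng(1)
        vals = np.exp(rng.normal(0, 0.05, size=(300, 3, len(GRID))))
        vals[:, :, 0] = 1.0
        signal = np.exp(0.5 * np.minimum(GRID / 20, 1))
        vals[7, 1, 1:] *= signal[1:]  # ~10 sigma at 6 of 7 times
        cube = make_cube(vals, [f"g{i}" for i in range(300)], list("abc"))
        res = ik.threshold_noise(cube)
        sel = res.selected.set_index(["gene", "experiment"])["selected"]
        assert sel.loc[("g7", "b")]
        assert np.array_equal(
            res.cube.values.loc["g7", "b"].to_numpy(), cube.values.loc["g7", "b"].to_numpy()
        )

    def test_output_is_input_or_exact_zero(self):
        rng = np.random.default_rng(2)
        vals = np.exp(rng.normal(0, 0.1, size=(100, 3, len(GRID))))
        vals[:, :, 0] = 1.0
        cube = make_cube(vals, [f"g{i}" for i in range(100)], list("abc"))
        res = ik.threshold_noise(cube)
        out, inp = res.cube.values.to_numpy(), cube.values.to_numpy()
        assert np.all((out == inp) | (out == 1.0))


class TestFullChain:
    def test_zero_noise_chain_is_identity_up_to_stress(self, artifact_sim):
        """With artifacts absent and no noise, cleaning reproduces the
        simulated cube; a shared stress signature is removed to 1e-9."""
        cube = artifact_sim["cube"]
        stress = 1.0 + 0.15 * np.exp(-(((GRID - 15) / 20.0) ** 2))
        stress[0] = 1.0
        spec = ik.NoiseSpec(gene_log_sd=0.0, array_log_sd=0.0, spot_log_sd=0.0,
                            stress_signature={"GEV": stress, "ZEV": stress})
        noisy = ik.corrupt_with_noise(cube, spec, artifact_sim["class_map"])
        spots, _ = ik.render_spot_table(noisy, ik.NoiseSpec(spot_log_sd=0.0, seed=1))
        res = ik.clean_pipeline(spots, artifact_sim["class_map"], apply_threshold=False)
        # expected output: the stress cancels exactly, leaving the noise-free
        # cube after its own class-median subtraction
        expected, _ = ik.subtract_class_median(cube, artifact_sim["class_map"])
        got = res.cube.values.loc[cube.genes].to_numpy()
        assert np.abs(np.log(got) - np.log(expected.values.to_numpy())).max() < 1e-9
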