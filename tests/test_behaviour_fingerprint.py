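"""Bout decomposition, behavioural parameters, fingerprints and statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from f0screen import behaviour_fingerprint as bf


class TestExtractBouts:
    def test_manual_run_length_example(self):
        bouts = bf.extract_bouts(np.array([0, 0, 5, 3, 0]), frame_rate=25.0)
        kinds = [(b.kind, b.start, b.end) for b in bouts]
        assert kinds == [("inactive", 0, 2), ("active", 2, 4), ("inactive", 4, 5)]
        assert bouts[1].duration == pytest.approx(2 / 25.0)
        assert bouts[1].values == (5, 3)

    def test_all_zero_trace_is_one_inactive_bout(self):
        bouts = bf.extract_bouts(np.zeros(10), 25.0)
        assert len(bouts) == 1 and bouts[0].kind == "inactive"
        assert (bouts[0].start, bouts[0].end) == (0, 10)

    def test_all_positive_trace_is_one_active_bout(self):
        bouts = bf.extract_bouts(np.ones(7), 25.0)
        assert len(bouts) == 1 and bouts[0].kind == "active"

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            bf.extract_bouts(np.array([1, -2, 0]), 25.0)

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_bouts_tile_trace_exactly(self, values):
        trace = np.array(values)
        bouts = bf.extract_bouts(trace, 10.0)
        assert bouts[0].start == 0 and bouts[-1].end == trace.size
        for prev, nxt in zip(bouts, bouts[1:]):
            assert prev.end == nxt.start
            assert prev.kind != nxt.kind


class TestBinAndSmooth:
    def test_constant_trace_sums_per_second(self):
        out = bf.bin_and_smooth(np.ones(250), frame_rate=25.0, smooth_minutes=1 / 60)
        assert out == pytest.approx(np.full(10, 25.0))

    def test_all_zero_stays_zero(self):
        assert bf.bin_and_smooth(np.zeros(100), 25.0).sum() == 0.0

    def test_rolling_average_of_constant_is_constant(self):
        out = bf.bin_and_smooth(np.full(25 * 120, 2.0), 25.0, smooth_minutes=1.0)
        assert out == pytest.approx(np.full(120, 50.0))


def _single_epoch(n_frames, label="day"):
    return [bf.Epoch(label, 0, 0, n_frames, habituation=False)]


class TestComputeParameters:
    def test_single_active_bout_arithmetic(self):
        trace = np.array([0, 5, 3, 0, 0])
        params = bf.compute_parameters(trace, _single_epoch(5), frame_rate=25.0)
        day = params.xs("day", level="epoch")
        assert day["active_bout_mean"] == pytest.approx(4.0)
        assert day["active_bout_total"] == pytest.approx(8.0)
        assert day["active_bout_min"] == pytest.approx(3.0)
        assert day["active_bout_max"] == pytest.approx(5.0)
        assert day["n_active_bouts"] == 1
        assert day["active_bout_length"] == pytest.approx(2 / 25.0)

    def test_all_zero_night_gives_zero_percent_and_missing_bout_stats(self):
        params = bf.compute_parameters(
            np.zeros(100), _single_epoch(100, "night"), frame_rate=25.0
        )
        night = params.xs("night", level="epoch")
        assert night["total_time_active_pct"] == 0.0
        assert night["total_activity"] == 0.0
        assert math.isnan(night["active_bout_mean"])

    def test_half_active_trace_is_fifty_percent(self):
        trace = np.tile([1, 0], 500)
        params = bf.compute_parameters(trace, _single_epoch(1000), 25.0)
        assert params[("total_time_active_pct", "day")] == pytest.approx(50.0)

    def test_habituation_epochs_cropped(self):
        trace = np.concatenate([np.full(50, 9), np.zeros(50)])
        epochs = [
            bf.Epoch("day", 0, 0, 50, habituation=True),
            bf.Epoch("day", 2, 50, 100, habituation=False),
        ]
        params = bf.compute_parameters(trace, epochs, 25.0)
        assert params[("total_activity", "day")] == 0.0

    @given(st.lists(st.integers(0, 4), min_size=20, max_size=120))
    @settings(max_examples=50, deadline=None)
    def test_active_bout_totals_sum_to_total_activity(self, values):
        trace = np.array(values)
        params = bf.compute_parameters(trace, _single_epoch(trace.size), 25.0)
        n = params[("n_active_bouts", "day")]
        if n > 0:
            mean_total = params[("active_bout_total", "day")]
            assert n * mean_total == pytest.approx(params[("total_activity", "day")])
        else:
            assert params[("total_activity", "day")] == 0.0


class TestBuildEpochs:
    def test_fourteen_ten_schedule_tiling(self):
        fr = 1.0
        n = int(48 * 3600 * fr)
        epochs = bf.build_epochs(n, fr)
        assert [e.label for e in epochs] == ["day", "night", "day", "night"]
        assert epochs[0].habituation and epochs[1].habituation
        assert not epochs[2].habituation
        assert epochs[0].end_frame == 14 * 3600
        assert epochs[-1].end_frame == n


class TestFingerprint:
    @pytest.fixture()
    def wt_params(self):
        rng = np.random.default_rng(0)
        cols = pd.MultiIndex.from_product(
            [bf.PARAMETERS, ["day", "night"]], names=["parameter", "epoch"]
        )
        return pd.DataFrame(
            rng.normal(10, 2, (12, len(cols))), columns=cols,
            index=[f"wt{i}" for i in range(12)],
        )

    def test_mutant_at_wt_mean_has_zero_fingerprint(self, wt_params):
        mutant = wt_params.mean().to_frame().T
        z = bf.fingerprint(mutant, wt_params)
        assert np.allclose(z.to_numpy(), 0.0)

    def test_one_sd_shift_gives_unit_z(self, wt_params):
        col = ("total_activity", "day")
        mutant = wt_params.mean().to_frame().T
        mutant[col] += wt_params[col].std(ddof=1)
        z = bf.fingerprint(mutant, wt_params)
        assert z.iloc[0][col] == pytest.approx(1.0)
        others = z.drop(columns=[col])
        assert np.allclose(others.to_numpy(), 0.0)

    def test_wildtype_self_fingerprint_mean_is_zero(self, wt_params):
        z = bf.fingerprint(wt_params, wt_params)
        assert np.allclose(z.mean().to_numpy(), 0.0, atol=1e-12)

    def test_zero_wt_sd_flagged_as_nan(self, wt_params):
        frozen = wt_params.copy()
        frozen[("active_bout_min", "day")] = 1.0
        z = bf.fingerprint(frozen.iloc[:2], frozen)
        assert z[("active_bout_min", "day")].isna().all()

    def test_single_wildtype_rejected(self, wt_params):
        with pytest.raises(ValueError):
            bf.fingerprint(wt_params, wt_params.iloc[:1])


class TestDistancesAndPearson:
    def test_unit_offset_on_k_parameters_gives_sqrt_k(self):
        cols = pd.MultiIndex.from_product([bf.PARAMETERS, ["day", "night"]])
        z = pd.DataFrame(0.0, index=["m1"], columns=cols)
        z.iloc[0, :4] = 1.0
        assert bf.euclidean_distances(z).iloc[0] == pytest.approx(2.0)

    def test_missing_parameters_rescaled(self):
        cols = pd.MultiIndex.from_product([bf.PARAMETERS, ["day", "night"]])
        z = pd.DataFrame(1.0, index=["m1"], columns=cols)
        z.iloc[0, 10:] = np.nan  # half the parameters missing
        # distance over 10 used entries rescaled by sqrt(20/10)
        assert bf.euclidean_distances(z).iloc[0] == pytest.approx(
            math.sqrt(10) * math.sqrt(2.0)
        )

    def test_identical_mean_fingerprints_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        fp = pd.Series(rng.normal(0, 1, 20))
        r = bf.fingerprint_pearson({"a": fp, "b": fp.copy()})
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_sign_flipped_fingerprint_anticorrelates(self):
        rng = np.random.default_rng(2)
        fp = pd.Series(rng.normal(0, 1, 20))
        r = bf.fingerprint_pearson({"a": fp, "b": -fp})
        assert r.loc["a", "b"] == pytest.approx(-1.0)


class TestGroupStats:
    def test_identical_groups_non_significant(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, 60)
        groups = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        report = bf.group_stats(values, groups)
        assert report.anova_p > 0.05
        assert (report.pairwise["p_holm"] > 0.05).all()

    def test_welch_p_matches_summary_statistics_oracle(self):
        # closed-form Welch t and Satterthwaite df from printed summaries
        rng = np.random.default_rng(4)

        def exact_sample(n, mean, sd):
            x = rng.normal(0, 1, n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x

        a = exact_sample(24, 5.0, 2.0)
        b = exact_sample(18, 3.2, 3.1)
        report = bf.group_stats(
            np.concatenate([a, b]), ["a"] * 24 + ["b"] * 18
        )
        va, vb = 2.0**2 / 24, 3.1**2 / 18
        t = (5.0 - 3.2) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 23 + vb**2 / 17)
        p = 2 * stats.t.sf(abs(t), df)
        row = report.pairwise.iloc[0]
        assert row["t"] == pytest.approx(abs(t), rel=1e-6)
        assert row["p"] == pytest.approx(p, rel=1e-6)

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(5)
        values = np.concatenate(
            [rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(3, 1, 15)]
        )
        groups = sum([[g] * 15 for g in "abcd"], [])
        report = bf.group_stats(values, groups)
        ordered = report.pairwise.sort_values("p")
        assert (np.diff(ordered["p_holm"]) >= -1e-12).all()
        assert (report.pairwise["p_holm"] >= report.pairwise["p"] - 1e-12).all()

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            bf.group_stats([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_two_way_anova_detects_interaction(self):
        rng = np.random.default_rng(6)
        rows = []
        for cond in ("wt", "ko"):
            for time in ("day", "night"):
                shift = 3.0 if (cond == "ko" and time == "day") else 0.0
                for v in rng.normal(shift, 1.0, 25):
                    rows.append({"value": v, "condition": cond, "time": time})
        table = bf.two_way_anova(pd.DataFrame(rows))
        inter_p = table.loc["C(condition):C(time)", "PR(>F)"]
        assert inter_p < 1e-6


class TestEffectSizeComparison:
    def test_identical_comparisons_give_zero(self):
        z, p = bf.effect_size_comparison(1.0, 30, 30, 1.0, 30, 30)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # d_a = 1, d_b = 0.5, n = 100 per group in both studies
        se = lambda d: math.sqrt(200 / (100 * 100) + d * d / 400)  # noqa: E731
        expected_z = (1.0 - 0.5) / math.sqrt(se(1.0) ** 2 + se(0.5) ** 2)
        z, p = bf.effect_size_comparison(1.0, 100, 100, 0.5, 100, 100)
        assert z == pytest.approx(expected_z)
        assert p == pytest.approx(2 * stats.norm.sf(abs(expected_z)))

    def test_swapping_comparisons_flips_sign(self):
        z1, p1 = bf.effect_size_comparison(1.2, 40, 35, 0.3, 50, 45)
        z2, p2 = bf.effect_size_comparison(0.3, 50, 45, 1.2, 40, 35)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            bf.effect_size_comparison(1.0, 1, 30, 1.0, 30, 30)
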