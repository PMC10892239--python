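"""Standardization, gated contrasts, FDR, RT analyses, screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import olfalert as oa
from conftest import synthetic_std_table
from olfalert import stats as ost
from olfalert import synthdata as sd


def metric_rows(values, **over):
    base = dict(
        subject_id="S00", condition="alerting", epoch_group=6,
        channel="F3", band="alpha", metric="PSD",
    )
    return pd.DataFrame(
        [dict(base, **over, trial_index=i, value=v) for i, v in enumerate(values)]
    )


def rt_events(n_subjects, seed, **cfg_over):
    cfg = sd.SimConfig(n_subjects=n_subjects, seed=seed, **cfg_over)
    rows = []
    for k in range(n_subjects):
        for cond in sd.CONDITIONS:
            beh = sd.generate_behavioral(cfg, f"S{k:02d}", cond)
            rows += [
                {"subject": f"S{k:02d}", "condition": cond, "time_s": t, "rt_s": rt}
                for t, rt in zip(beh.trial_times_s, beh.rt_s)
            ]
    return pd.DataFrame(rows)


class TestEpochAverage:
    def test_simple_mean(self):
        out = ost.epoch_average(ost.trials_to_frame(metric_rows([2.0, 4.0]).to_dict("records")))
        assert out["value_raw"].iloc[0] == 3.0
        assert out["n_trials"].iloc[0] == 2

    def test_single_trial_epoch(self):
        out = ost.epoch_average(metric_rows([5.0]))
        assert out["value_raw"].iloc[0] == 5.0

    def test_mean_over_survivors_with_count(self):
        # a dropped trial simply is not present in the rows
        out = ost.epoch_average(metric_rows([1.0, 2.0, 6.0]).iloc[[0, 2]])
        assert out["value_raw"].iloc[0] == 3.5
        assert out["n_trials"].iloc[0] == 2


class TestStandardizeBaseline:
    @staticmethod
    def means(baseline, value):
        rows = []
        for e, v in ((5, baseline), (6, value)):
            rows.append(
                dict(subject_id="S00", condition="alerting", epoch_group=e,
                     channel="F3", band="alpha", metric="PSD", value_raw=v,
                     n_trials=10)
            )
        return pd.DataFrame(rows)

    def test_ratio(self):
        out, log = ost.standardize_baseline(self.means(2.0, 3.0))
        assert out.loc[out.epoch_group == 6, "value_std"].iloc[0] == 1.5
        assert log == []

    def test_baseline_epoch_is_one(self):
        out, _ = ost.standardize_baseline(self.means(2.0, 3.0))
        assert out.loc[out.epoch_group == 5, "value_std"].iloc[0] == 1.0

    def test_zero_baseline_marked_missing_and_logged(self):
        out, log = ost.standardize_baseline(self.means(0.0, 3.0))
        assert out["value_std"].isna().all()
        assert len(log) == 1 and "F3" in log[0]

    @given(c=st.floats(min_value=0.01, max_value=1000))
    def test_scale_invariance(self, c):
        base, _ = ost.standardize_baseline(self.means(2.0, 3.0))
        scaled, _ = ost.standardize_baseline(self.means(2.0 * c, 3.0 * c))
        np.testing.assert_allclose(
            scaled["value_std"].to_numpy(), base["value_std"].to_numpy(), rtol=1e-9
        )


class TestBhFdr:
    def test_uniform_family(self):
        adj, flags = ost.bh_fdr([0.01] * 19)
        np.testing.assert_allclose(adj, 0.01)
        assert flags.all()

    def test_single_small_p(self):
        p = [0.001] + [0.5] * 18
        adj, flags = ost.bh_fdr(p)
        assert adj[0] == pytest.approx(0.001 * 19, rel=1e-9)  # 0.019
        assert flags[0] and not flags[1:].any()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ost.bh_fdr([])

    @given(
        p=st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40)
    )
    def test_adjusted_at_least_raw_and_flag_consistency(self, p):
        adj, flags = ost.bh_fdr(p, alpha=0.05)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj[flags] < 0.05 + 1e-12)

    def test_null_calibration_small(self):
        rng = np.random.default_rng(0)
        fdp = []
        for _ in range(300):
            _, flags = ost.bh_fdr(rng.uniform(size=19), alpha=0.05)
            fdp.append(1.0 if flags.any() else 0.0)
        se = np.sqrt(0.05 * 0.95 / 300)
        assert np.mean(fdp) <= 0.05 + 2 * se


class TestConditionContrast:
    def test_always_enumerates_475_candidates(self):
        table = ost.condition_contrast(synthetic_std_table(n_subjects=4))
        assert len(table) == 475
        assert table.groupby(["metric", "band"]).size().eq(19).all()

    def test_sparse_input_still_full_grid_with_reasons(self):
        df = synthetic_std_table(n_subjects=4)
        df = df[df["band"] == "alpha"]
        table = ost.condition_contrast(df)
        assert len(table) == 475
        skipped = table[table["p_raw"].isna()]
        assert (skipped["reason"] != "").all()

    def test_identical_conditions_null_convention(self):
        df = synthetic_std_table(n_subjects=5)
        relax = df[df.condition == "relaxing"].copy()
        df.loc[df.condition == "alerting", "value_std"] = relax["value_std"].to_numpy()
        table = ost.condition_contrast(df)
        row = table[(table.metric == "PSD") & (table.band == "alpha")].iloc[0]
        assert row["p_raw"] == 1.0 and row["statistic"] == 0.0

    def test_paired_t_df_89_for_30_subjects_3_epochs(self):
        rng = np.random.default_rng(1)
        df = synthetic_std_table(n_subjects=30, rng=rng)
        table = ost.condition_contrast(df)
        t_rows = table[table["test_used"] == "paired_t"]
        assert not t_rows.empty
        assert (t_rows["df"] == 89).all()
        assert (table["n_pairs"] == 90).all()

    def test_shapiro_gate_routes_skewed_data_to_wilcoxon(self):
        rng = np.random.default_rng(2)
        gated = 0
        for _ in range(100):
            diffs = rng.exponential(size=90)
            res = ost._paired_test(diffs)
            gated += res["test_used"] == "wilcoxon"
        assert gated >= 90

    def test_significant_implies_adjusted_below_alpha(self, engineered_cohort):
        std_table, _ = engineered_cohort
        table = ost.condition_contrast(std_table)
        sig = table[table["significant"]]
        assert not sig.empty
        assert (sig["p_adjusted"] < 0.05).all()
        assert (
            table.dropna(subset=["p_raw"])["p_adjusted"]
            >= table.dropna(subset=["p_raw"])["p_raw"] - 1e-12
        ).all()


class TestRtAnalyses:
    def test_rt_table_piecewise_standardization(self):
        rows = []
        for e, rt in [(0, 0.5), (3, 0.6), (5, 0.8), (7, 1.0)]:
            rows.append({"subject": "S00", "condition": "alerting",
                         "time_s": e * 300.0 + 20.0, "rt_s": rt})
        table = ost.rt_epoch_table(pd.DataFrame(rows))
        by_epoch = table.set_index("epoch_group")["rt_mean_std"]
        assert by_epoch[0] == 1.0
        assert by_epoch[3] == pytest.approx(0.6 / 0.5)
        assert by_epoch[5] == pytest.approx(0.8 / 0.5)  # pre-onset: epoch-0 base
        assert by_epoch[7] == pytest.approx(1.0 / 0.8)  # post-onset: epoch-5 base

    def test_window_contrast_df_and_sign(self):
        table = ost.rt_epoch_table(rt_events(30, seed=0))
        res = ost.rt_contrast(table, window=(6, 7, 8))
        assert res["df"] == 89
        assert res["t"] < 0  # alerting faster than relaxing

    def test_default_effect_power_and_null_calibration(self):
        # The epoch-pooled variant carries the published df; null
        # calibration is checked on the subject-pooled variant (the
        # epoch-pooled one shares baselines across pairs and is
        # anticonservative under the null by construction).
        sig, null_sig, pre_sig = 0, 0, 0
        for seed in range(50):
            table = ost.rt_epoch_table(rt_events(30, seed=seed, rt_noise_sigma=0.1))
            sig += ost.rt_contrast(table, window=(6, 7, 8))["p"] < 0.01
            pre = ost.rt_contrast(
                table, window=(1, 2, 3, 4, 5), pooling="subjects"
            )
            pre_sig += pre["p"] < 0.05
            null_table = ost.rt_epoch_table(
                rt_events(30, seed=seed + 1000, rt_effect_s=0.0)
            )
            null_sig += (
                ost.rt_contrast(null_table, window=(6, 7, 8), pooling="subjects")["p"]
                < 0.05
            )
        assert sig >= 45  # >= 90% power at the injected effect
        assert pre_sig <= 5  # pre-onset window behaves as a null
        assert null_sig <= 5

    def test_subject_pooling_df(self):
        table = ost.rt_epoch_table(rt_events(30, seed=1))
        res = ost.rt_contrast(table, window=(6, 7, 8), pooling="subjects")
        assert res["df"] == 29

    def test_anova_interaction_from_decaying_effect(self):
        hits = 0
        for seed in range(50):
            table = ost.rt_epoch_table(rt_events(30, seed=seed, rt_noise_sigma=0.1))
            res = ost.rt_anova(table, window=tuple(range(6, 12)))
            hits += res.loc["condition_x_epoch", "p"] < 0.05
        assert hits >= 40  # >= 80% of replicates

    def test_anova_constant_shift_has_no_interaction(self):
        rng = np.random.default_rng(3)
        fs = []
        for _ in range(50):
            rows = []
            for k in range(12):
                for cond in sd.CONDITIONS:
                    shift = 0.2 if cond == "relaxing" else 0.0
                    for e in range(6, 10):
                        rows.append(
                            {"subject": f"S{k}", "condition": cond, "epoch_group": e,
                             "rt_mean_std": 1.0 + shift + rng.normal(0, 0.1)}
                        )
            table = pd.DataFrame(rows)
            res = ost.rt_anova(table, window=tuple(range(6, 10)))
            assert res.loc["condition", "p"] < 0.05
            fs.append(res.loc["condition_x_epoch", "F"])
        assert np.mean(fs) == pytest.approx(1.0, abs=0.35)

    def test_anova_all_equal_data_zero_f(self):
        rows = [
            {"subject": f"S{k}", "condition": c, "epoch_group": e, "rt_mean_std": 1.0}
            for k in range(6) for c in sd.CONDITIONS for e in (6, 7)
        ]
        res = ost.rt_anova(pd.DataFrame(rows), window=(6, 7))
        assert (res["F"] == 0).all()

    def test_anova_missing_cells_listed(self):
        rows = [
            {"subject": f"S{k}", "condition": c, "epoch_group": e, "rt_mean_std": 1.0}
            for k in range(4) for c in sd.CONDITIONS for e in (6, 7)
        ]
        df = pd.DataFrame(rows).iloc[:-1]
        with pytest.raises(ValueError, match="missing cells"):
            ost.rt_anova(df, window=(6, 7))


class TestRtMetricCorrelation:
    @staticmethod
    def tables(rng, n_subjects=12, couple_channel=None):
        rows, rt_rows = [], []
        for k in range(n_subjects):
            for cond in sd.CONDITIONS:
                for e in (6, 7, 8):
                    rt = 1.0 + rng.normal(0, 0.1)
                    rt_rows.append({"subject": f"S{k:02d}", "condition": cond,
                                    "epoch_group": e, "rt_mean_raw": rt,
                                    "rt_mean_std": rt})
                    for ch in oa.CHANNELS_1020:
                        v = 1.0 + rng.normal(0, 0.1)
                        if ch == couple_channel:
                            v = rt + rng.normal(0, 0.02)
                        rows.append({"subject_id": f"S{k:02d}", "condition": cond,
                                     "epoch_group": e, "channel": ch,
                                     "band": "alpha", "metric": "PSD",
                                     "value_raw": v, "value_std": v})
        return pd.DataFrame(rows), pd.DataFrame(rt_rows)

    def test_identity_column_r_one(self):
        std, rt = self.tables(np.random.default_rng(0), couple_channel="F8")
        std.loc[std.channel == "F8", "value_std"] = (
            std[std.channel == "F8"]
            .merge(rt, left_on=["subject_id", "condition", "epoch_group"],
                   right_on=["subject", "condition", "epoch_group"])["rt_mean_std"]
            .to_numpy()
        )
        out = ost.rt_metric_correlation(std, rt, metrics=("PSD",))
        row = out[(out.metric == "PSD") & (out.channel == "F8")].iloc[0]
        assert row["r"] == pytest.approx(1.0)

    def test_null_false_positive_rate_controlled(self):
        rng = np.random.default_rng(1)
        flagged, total = 0, 0
        for _ in range(60):
            std, rt = self.tables(rng)
            out = ost.rt_metric_correlation(std, rt, metrics=("PSD",))
            flagged += int(out["significant"].sum())
            total += len(out)
        assert flagged / total <= 0.05

    def test_generator_coupling_flagged_at_f8(self):
        hits = 0
        for seed in range(50):
            sim = sd.SimConfig(
                n_subjects=8, fs_hz=125.0, seed=seed, artifacts_enabled=False,
                rt_alpha_coupling=0.6, alpha_fluct_sigma=0.4, rt_noise_sigma=0.08,
                alpha_suppression=0.0, rt_effect_s=0.0,
            )
            std, events = oa.pipeline.simulate_cohort_metrics(
                sim, epochs=(5, 6, 7, 8), trials_per_epoch=2
            )
            rt = ost.rt_epoch_table(events)
            out = ost.rt_metric_correlation(std, rt, metrics=("PSD",), min_pairs=10)
            row = out[(out.metric == "PSD") & (out.channel == "F8")].iloc[0]
            hits += bool(row["significant"] and row["r"] > 0)
        assert hits > 25  # positive, FDR-flagged coupling in the majority of seeds

    def test_insufficient_pairs_skipped(self):
        std, rt = self.tables(np.random.default_rng(2), n_subjects=1)
        out = ost.rt_metric_correlation(std, rt, metrics=("PSD",), min_pairs=10)
        assert (out["reason"] == "insufficient pairs").all()


class TestSactExclusion:
    def test_identical_sessions_kept(self):
        rng = np.random.default_rng(0)
        rtx = rng.normal(0.4, 0.05, 64)
        out = ost.sact_exclusion((60, 4), (60, 4), rtx, rtx)
        assert not out["drop"]

    def test_accuracy_table_significance(self):
        rng = np.random.default_rng(3)
        rtx = rng.normal(0.4, 0.05, 64)
        out = ost.sact_exclusion((60, 4), (40, 24), rtx, rtx)
        assert out["p_accuracy"] < 0.05

    def test_conjunction_rule_keeps_on_equal_rt(self):
        rng = np.random.default_rng(1)
        rtx = rng.normal(0.4, 0.05, 64)
        out = ost.sact_exclusion((60, 4), (40, 24), rtx, rtx)
        assert out["p_accuracy"] < 0.05 and not out["drop"]

    def test_both_criteria_drop(self):
        rng = np.random.default_rng(2)
        out = ost.sact_exclusion(
            (60, 4), (40, 24),
            rng.normal(0.40, 0.05, 64), rng.normal(0.55, 0.05, 64),
        )
        assert out["drop"]

    def test_degenerate_table_kept_logged(self):
        out = ost.sact_exclusion((64, 0), (64, 0), np.ones(64), np.ones(64))
        assert not out["drop"] and out["log"]


class TestCountSignificant:
    def test_fixture_counts(self, table2):
        counts = ost.count_significant(table2)
        assert counts == {
            "n_candidates": 475, "n_significant": 108, "n_frontal_parietal": 76,
        }

    def test_empty_significance(self):
        table = ost.condition_contrast(synthetic_std_table(n_subjects=4).iloc[:0])
        counts = ost.count_significant(table)
        assert counts == {
            "n_candidates": 475, "n_significant": 0, "n_frontal_parietal": 0,
        }
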