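"""ANOVA, Tukey HSD and the cross-validated ablation harness."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qtremor import ablation as ab
from qtremor import synthdata as sd


class TestAnova:
    def test_identical_constant_groups(self):
        res = ab.anova_oneway([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        assert res.ss_between == pytest.approx(0.0, abs=1e-12)
        assert res.f_stat == 0.0

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.6, 1, 9)
        res = ab.anova_oneway([a, b])
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_stat == pytest.approx(t**2, abs=1e-9)

    def test_matches_brute_force_sums_of_squares(self, rng):
        groups = [rng.normal(m, 1, 5) for m in (0.0, 0.5, 1.0)]
        res = ab.anova_oneway(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = ssw = 0.0
        for g in groups:
            gm = g.mean()
            ssb += len(g) * (gm - grand) ** 2
            for v in g:
                ssw += (v - gm) ** 2
        assert res.ss_between == pytest.approx(ssb, abs=1e-10)
        assert res.ss_within == pytest.approx(ssw, abs=1e-10)
        assert res.df_between == 2 and res.df_within == 12

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(m, 1, 8) for m in (0, 0.3, 0.9, 1.4)]
        res = ab.anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert res.f_stat == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_sum_of_squares_conservation(self, rng):
        groups = [rng.normal(m, 2, 20) for m in (0, 1, 2, 5, 9)]
        res = ab.anova_oneway(groups)
        total = ((np.concatenate(groups) - np.concatenate(groups).mean()) ** 2).sum()
        assert res.ss_between + res.ss_within == pytest.approx(total, abs=1e-9)

    def test_default_replicate_scheme_degrees_of_freedom(self, rng):
        # 6 configurations x (10 folds x 10 repeats) -> dfs (5, 594)
        groups = [rng.normal(m, 1, 100) for m in range(6)]
        res = ab.anova_oneway(groups)
        assert (res.df_between, res.df_within) == (5, 594)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ab.anova_oneway([[1.0, 2.0]])
        with pytest.raises(ValueError):
            ab.anova_oneway([[1.0], [2.0, 3.0]])


class TestTukey:
    def test_six_groups_give_fifteen_rows(self, rng):
        groups = [rng.normal(m, 1, 10) for m in range(6)]
        rows = ab.tukey_hsd(groups)
        assert len(rows) == 15

    def test_identical_groups_nothing_significant(self, rng):
        g = rng.normal(0, 1, 10)
        rows = ab.tukey_hsd([g.copy(), g.copy(), g.copy()])
        assert all(not r.significant for r in rows)
        assert all(r.mean_diff == pytest.approx(0.0, abs=1e-12) for r in rows)

    def test_mean_difference_is_definitional(self, rng):
        groups = [rng.normal(m, 1, 7) for m in (0.0, 1.0, 3.5)]
        means = [g.mean() for g in groups]
        for r in ab.tukey_hsd(groups):
            assert r.mean_diff == pytest.approx(means[r.group2] - means[r.group1],
                                                abs=1e-12)

    def test_ci_brackets_mean_difference_and_matches_flag(self, rng):
        groups = [rng.normal(m, 1, 12) for m in (0, 0.2, 2.0, 2.1)]
        for r in ab.tukey_hsd(groups):
            assert r.ci_low <= r.mean_diff <= r.ci_high
            excludes_zero = r.ci_low > 0 or r.ci_high < 0
            assert r.significant == excludes_zero
            assert r.significant == (r.p_value < 0.05)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = [rng.normal(m, 1.0, 11) for m in (0.0, 0.8, 1.5)]
        values = np.concatenate(groups)
        labels = np.repeat([0, 1, 2], 11)
        ref = pairwise_tukeyhsd(values, labels, alpha=0.05)
        ours = ab.tukey_hsd(groups)
        ref_table = np.asarray(ref.summary().data[1:], dtype=object)
        for row, (r_meandiff, r_p, r_lo, r_hi) in zip(
                ours, zip(ref.meandiffs, ref.pvalues,
                          ref.confint[:, 0], ref.confint[:, 1])):
            assert row.mean_diff == pytest.approx(r_meandiff, abs=1e-10)
            assert row.p_value == pytest.approx(r_p, abs=1e-6)
            assert row.ci_low == pytest.approx(r_lo, abs=1e-8)
            assert row.ci_high == pytest.approx(r_hi, abs=1e-8)

    def test_monotone_power_in_group_shift(self, rng):
        base = [rng.normal(0, 1, 10) for _ in range(3)]
        base = [g - g.mean() for g in base]  # so |mean diff| equals the shift
        prev_p = None
        prev_diff = None
        for shift in (0.5, 1.0, 1.5):
            groups = [base[0] + shift, base[1].copy(), base[2].copy()]
            rows = {(r.group1, r.group2): r for r in ab.tukey_hsd(groups)}
            p01, d01 = rows[(0, 1)].p_value, abs(rows[(0, 1)].mean_diff)
            if prev_p is not None:
                assert d01 > prev_diff
                assert p01 <= prev_p
            prev_p, prev_diff = p01, d01

    def test_pairwise_mean_differences_convention(self):
        means = [10.0, 7.0, 1.0]
        d = ab.pairwise_mean_differences(means)
        assert d[(0, 1)] == pytest.approx(-3.0)
        assert d[(1, 2)] == pytest.approx(-6.0)
        assert d[(0, 2)] == pytest.approx(-9.0)
        assert set(d) == set(itertools.combinations(range(3), 2))


class TestSummarize:
    def _rows(self, values):
        rows = []
        for cfg, vals in values.items():
            for i, v in enumerate(vals):
                rows.append({"config": cfg, "label": "x", "fold": i, "repeat": 0,
                             "train_loss": v, "train_accuracy": v, "val_loss": v,
                             "val_accuracy": v, "test_loss": v, "test_accuracy": v,
                             "seconds": 1.0, "seed": i})
        return pd.DataFrame(rows)

    def test_constant_metric(self):
        out = ab.summarize(self._rows({0: [0.5, 0.5], 1: [0.5, 0.5]}))
        assert out["test_accuracy_mean"].tolist() == [0.5, 0.5]
        assert out["test_accuracy_std"].tolist() == [0.0, 0.0]

    def test_two_value_std_uses_n_minus_one(self):
        out = ab.summarize(self._rows({0: [0.4, 0.6], 1: [0.4, 0.6]}))
        assert out["test_accuracy_mean"].iloc[0] == pytest.approx(0.5)
        assert out["test_accuracy_std"].iloc[0] == pytest.approx(0.1414, abs=1e-4)

    def test_one_row_per_config(self):
        out = ab.summarize(self._rows({i: [0.1, 0.2] for i in range(6)}))
        assert len(out) == 6

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            ab.summarize(self._rows({0: [0.5], 1: [0.5, 0.6]}))


@pytest.fixture(scope="module")
def tiny_run():
    ds = sd.generate_dataset(24, params=sd.SignalParams.well_separated(), seed=5)
    cfg = ab.AblationConfig(folds=2, repeats=1, epochs=1, resize=(16, 64),
                            base_seed=0)
    return ds, cfg, ab.run_ablation(ds, cfg)


class TestRunAblation:

    def test_row_cardinality(self, tiny_run):
        _, _, rows = tiny_run
        assert len(rows) == 6 * 2 * 1
        assert sorted(rows["config"].unique()) == [0, 1, 2, 3, 4, 5]

    def test_metrics_are_bounded(self, tiny_run):
        _, _, rows = tiny_run
        for col in ("train_accuracy", "val_accuracy", "test_accuracy"):
            assert rows[col].between(0, 1).all()
        for col in ("train_loss", "val_loss", "test_loss"):
            assert (rows[col] >= 0).all()

    def test_same_base_seed_reproduces_metrics(self, tiny_run):
        ds, cfg, rows = tiny_run
        again = ab.run_ablation(ds, cfg)
        pd.testing.assert_frame_equal(
            rows.drop(columns=["seconds"]), again.drop(columns=["seconds"]))

    def test_excessive_fold_count_rejected(self):
        ds = sd.generate_dataset(12, seed=1)
        with pytest.raises(ValueError):
            ab.run_ablation(ds, ab.AblationConfig(folds=10, repeats=1, epochs=1,
                                                  resize=(8, 32)))


class TestReport:
    def test_files_written_and_deterministic(self, tmp_path, rng):
        groups = [rng.normal(m, 1, 6) for m in range(6)]
        rows = []
        for cfg, g in enumerate(groups):
            for i, v in enumerate(g):
                rows.append({"config": cfg, "label": "x", "fold": i, "repeat": 0,
                             "train_loss": 0.1, "train_accuracy": 0.9,
                             "val_loss": 0.1, "val_accuracy": 0.9,
                             "test_loss": 0.1, "test_accuracy": v,
                             "seconds": 1.0, "seed": i})
        rows = pd.DataFrame(rows)
        summary = ab.summarize(rows)
        anova = ab.anova_oneway(groups)
        tukey = ab.tukey_hsd(groups)
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        p1 = ab.report(summary, anova, tukey, str(d1))
        p2 = ab.report(summary, anova, tukey, str(d2))
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()
        assert len(pd.read_csv(p1["tukey"])) == 15
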