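import numpy as np
import pandas as pd
import pytest

from puzzletrain import trial


@pytest.fixture(scope="module")
def fixtures():
    return trial.load_fixtures()


class TestFixtures:
    def test_first_participant_characteristics(self, fixtures):
        participants, _ = fixtures
        first = participants[0]
        assert (first.id, first.age, first.moca) == ("01", 75, 26)
        assert (first.tmt_a_s, first.tmt_b_s, first.smt_s) == (38, 119, 27)

    def test_cohort_size_and_groups(self, fixtures):
        participants, _ = fixtures
        assert len(participants) == 12
        assert sum(p.group == "control" for p in participants) == 7
        assert sum(p.group == "experimental" for p in participants) == 5
        assert "09" not in {p.id for p in participants}  # excluded enrollee

    def test_subscale_tables_have_twelve_rows(self, fixtures):
        _, table = fixtures
        assert len(table.imi) == len(table.tlx) == 12
        assert (table.imi.to_numpy() >= 0).all()
        assert (table.tlx.to_numpy() >= 0).all()

    def test_checksum_guard_detects_corruption(self, monkeypatch):
        monkeypatch.setitem(trial._CHECKSUMS, "imi.csv", "0" * 64)
        with pytest.raises(RuntimeError, match="corrupted"):
            trial.load_fixtures()


class TestSummarize:
    def test_cohort_age_matches_reported_demographics(self, fixtures):
        participants, _ = fixtures
        mean, sd = trial.summarize([p.age for p in participants])
        assert trial.round_half_up(mean) == 58.92
        assert trial.round_half_up(sd) == 10.28

    def test_constant_sample(self):
        assert trial.summarize([5, 5, 5]) == (5.0, 0.0)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            trial.summarize([5])

    def test_half_up_rounding_at_report_layer_only(self):
        assert trial.round_half_up(2.065) == 2.07
        assert trial.round_half_up(2.064) == 2.06


class TestShapiroWilk:
    def test_normal_quantile_sample_scores_high(self):
        from scipy.stats import norm

        sample = 50 + 10 * norm.ppf(np.linspace(0.04, 0.96, 12))
        w, _ = trial.shapiro_wilk(sample)
        assert w > 0.95

    def test_bimodal_sample_scores_low(self):
        w, p = trial.shapiro_wilk([0.0] * 6 + [100.0] * 6)
        assert w < 0.859  # 5% critical value for n = 12
        assert p < 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            trial.shapiro_wilk([3.0] * 12)

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            trial.shapiro_wilk([1.0, 2.0])

    def test_agrees_with_independent_reference_value(self):
        # shapiro.test in R on the same vector gives these values
        sample = [1.2, 3.4, 2.2, 5.5, 4.4, 3.3, 2.1, 0.5, 6.6, 1.1, 2.8, 3.9]
        w, p = trial.shapiro_wilk(sample)
        assert w == pytest.approx(0.9686284936, abs=1e-6)
        assert p == pytest.approx(0.8959171573, abs=1e-6)


class TestPairedT:
    def test_identical_vectors_rejected(self):
        with pytest.raises(ValueError):
            trial.paired_t([1, 2, 3], [1, 2, 3])

    def test_constant_shift_rejected(self):
        with pytest.raises(ValueError):
            trial.paired_t([1, 2, 3, 4], [2, 3, 4, 5])

    def test_matches_hand_computed_closed_form(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(50, 8, size=12)
        post = pre - rng.normal(2, 3, size=12)
        t, df, p = trial.paired_t(pre, post)
        d = pre - post
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy.stats import t as tdist

        assert df == 11
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(2 * tdist.sf(abs(t_hand), 11), rel=1e-10)


class TestRmAnova:
    def test_identical_waves_give_zero_f(self):
        data = np.tile(np.random.default_rng(1).normal(30, 5, size=(12, 1)), (1, 3))
        f, df1, df2, p = trial.rm_anova(data)
        assert f == 0.0 and p == 1.0

    def test_two_condition_contrast_matches_closed_form(self):
        # two identical waves plus one shifted wave: the condition and
        # residual sums of squares reduce to a two-condition contrast
        # computable by hand.
        base = np.array([10.0, 12.0, 14.0, 16.0])
        shift = np.array([3.0, 1.0, 4.0, 2.0])
        data = np.column_stack([base, base, base + shift])
        n, k = data.shape
        grand = data.mean()
        ss_cond = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k))
        ss_subj = k * sum((data[i, :].mean() - grand) ** 2 for i in range(n))
        ss_err = ((data - grand) ** 2).sum() - ss_cond - ss_subj
        f_hand = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        f, df1, df2, _ = trial.rm_anova(data)
        assert f == pytest.approx(f_hand, rel=1e-9)

    def test_degrees_of_freedom_for_three_waves(self):
        data = np.random.default_rng(2).normal(size=(12, 3))
        _, df1, df2, _ = trial.rm_anova(data)
        assert (df1, df2) == (2.0, 22.0)

    def test_missing_cells_rejected(self):
        data = np.random.default_rng(2).normal(size=(12, 3))
        data[0, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            trial.rm_anova(data)

    def test_greenhouse_geisser_shrinks_dfs(self):
        data = np.random.default_rng(3).normal(size=(12, 3))
        data[:, 2] += np.random.default_rng(4).normal(scale=5, size=12)
        _, df1, df2, _ = trial.rm_anova(data, correction="gg")
        assert df1 < 2.0 and df2 < 22.0


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = trial.pearson_r(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_orthogonal_pair_is_uncorrelated(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0]) - 1 / 3
        r, _ = trial.pearson_r(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        r, _ = trial.pearson_r(x, y)
        r_hand = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(r_hand, rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            trial.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSubscaleReport:
    def test_motivation_and_workload_orderings(self, fixtures):
        _, table = fixtures
        report = trial.subscale_report(table)
        imi = report[report.instrument == "imi"].set_index("subscale")
        tlx = report[report.instrument == "tlx"].set_index("subscale")
        assert imi.total.idxmax() == "interest_enjoyment"
        assert imi.total.idxmin() == "value_usefulness"
        assert tlx.total.idxmin() == "physical_demand"

    def test_report_totals_are_column_sums(self, fixtures):
        _, table = fixtures
        report = trial.subscale_report(table).set_index("subscale")
        assert report.loc["interest_enjoyment", "total"] == table.imi["interest_enjoyment"].sum()

    def test_pretest_summary_table_layout(self):
        frame = trial.pretest_summary_table()
        assert list(frame.columns) == ["measure", "wave", "mean", "sd"]
        assert set(frame.wave) == {"pre"}
        assert isinstance(frame, pd.DataFrame) and len(frame) == 5
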