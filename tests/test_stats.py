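"""Contingency tables, group comparisons, logistic fits, U-shape profiles."""

import numpy as np
import pandas as pd
import pytest

from frailcascade.pipeline import PUBLISHED_COUNTS, published_count_fixture
from frailcascade.stats import (SeparationError, chi_square, crosstab,
                                fit_logistic, fit_multinomial,
                                group_compare_continuous, ushape_profile)


@pytest.fixture(scope="module")
def fixture_frame():
    statuses, classes = published_count_fixture()
    return pd.DataFrame({
        "frailty_class": classes,
        "htn": [s.bp_category == "htn" for s in statuses],
    })


class TestCrosstab:
    def test_published_class_by_htn_counts(self, fixture_frame):
        tab = crosstab(fixture_frame, "frailty_class", "htn")
        expect = {"robust": (366, 355), "pre_frail": (669, 1038),
                  "frail": (620, 1304)}
        for cls, (no, yes) in expect.items():
            assert tab.loc[cls, False] == no and tab.loc[cls, True] == yes
        assert tab.to_numpy().sum() == PUBLISHED_COUNTS["n_total"]

    def test_single_class_table_rejected(self, fixture_frame):
        single = fixture_frame[fixture_frame["frailty_class"] == "frail"]
        with pytest.raises(ValueError, match="2x2"):
            crosstab(single, "frailty_class", "htn")

    def test_counts_conserved_under_random_labels(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.choice(list("xyz"), 500),
                           "b": rng.choice([0, 1, 2], 500)})
        df.loc[rng.choice(500, 30, replace=False), "b"] = None
        tab = crosstab(df, "a", "b")
        assert tab.to_numpy().sum() == df.dropna().shape[0]
        assert tab.attrs["n_undefined"] == df["b"].isna().sum()


class TestChiSquare:
    def test_proportional_table_is_exactly_null(self):
        stat, df, p = chi_square([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)
        assert df == 1

    def test_published_htn_table_highly_significant(self, fixture_frame):
        stat, df, p = chi_square(crosstab(fixture_frame, "frailty_class", "htn"))
        assert df == 2 and p < 0.001

    def test_zero_expected_count_advises(self):
        with pytest.raises(ValueError, match="collapse"):
            chi_square([[0, 0], [5, 10]])

    def test_p_agrees_with_sampled_permutation_null(self):
        """On small 2x2 tables the asymptotic p matches a 10,000-draw
        Monte-Carlo permutation mid-P up to the MC noise and the lattice
        granularity of the discrete null."""
        rng = np.random.default_rng(77)
        for _ in range(15):
            row_p = rng.dirichlet([10.0, 10.0])
            col_p = rng.dirichlet([10.0, 10.0])
            cells = rng.multinomial(400,
                                    np.outer(row_p, col_p).ravel()).reshape(2, 2)
            _, _, p = chi_square(cells)
            rows = np.repeat([0, 1], cells.sum(axis=1))
            cols = np.concatenate([np.repeat([0, 1], cells[i]) for i in (0, 1)])
            n = len(rows)
            expected = np.outer(cells.sum(axis=1), cells.sum(axis=0)) / n
            obs = ((cells - expected) ** 2 / expected).sum()
            perm = rng.permuted(np.tile(cols, (10_000, 1)), axis=1)
            k11 = ((rows == 0)[None, :] & (perm == 0)).sum(axis=1)
            counts = np.stack([
                np.stack([k11, cells.sum(axis=1)[0] - k11], axis=1),
                np.stack([cells.sum(axis=0)[0] - k11,
                          cells.sum(axis=1)[1] - (cells.sum(axis=0)[0] - k11)],
                         axis=1)], axis=1)
            stats_perm = ((counts - expected) ** 2 / expected).sum(axis=(1, 2))
            midp = (np.sum(stats_perm > obs + 1e-9)
                    + 0.5 * np.sum(np.abs(stats_perm - obs) <= 1e-9)) / 10_000
            assert abs(p - midp) < 0.06


class TestGroupCompare:
    def test_identical_groups_give_null_t(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0] * 2, "g": ["a"] * 3 + ["b"] * 3})
        cmp_ = group_compare_continuous(df, "v", "g")
        assert cmp_.test == "t"
        assert cmp_.statistic == pytest.approx(0.0) and cmp_.p == pytest.approx(1.0)

    def test_three_equal_groups_type_one_error_near_alpha(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 400
        for _ in range(reps):
            df = pd.DataFrame({"v": rng.standard_normal(90),
                               "g": np.repeat(["a", "b", "c"], 30)})
            cmp_ = group_compare_continuous(df, "v", "g")
            assert cmp_.test == "anova"
            rejections += cmp_.p < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_planted_dbp_gradient_detected_at_5000(self):
        from frailcascade.cohort import RunConfig
        from frailcascade.pipeline import build_analysis_frame
        from frailcascade.simulate import GeneratorParams, generate_cohort
        records, _ = generate_cohort(GeneratorParams(n=5000, seed=31))
        df = build_analysis_frame(records, RunConfig())
        cmp_ = group_compare_continuous(df, "dbp", "frailty_class")
        assert cmp_.test == "anova" and cmp_.p < 0.05
        assert cmp_.means["frail"] < cmp_.means["robust"]

    def test_degenerate_group_error(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0], "g": ["a", "a", "b"]})
        with pytest.raises(ValueError):
            group_compare_continuous(df, "v", "g")


class TestLogistic:
    def test_intercept_only_equals_logit_of_prevalence(self):
        rng = np.random.default_rng(8)
        y = rng.random(2000) < 0.3
        df = pd.DataFrame({"y": y.astype(float)})
        fit = fit_logistic(df, "y", [])
        p_hat = y.mean()
        assert fit.term("intercept")["coef"] == pytest.approx(
            np.log(p_hat / (1 - p_hat)), abs=1e-6)

    def test_recovers_planted_coefficients(self):
        rng = np.random.default_rng(9)
        n = 8000
        x = rng.standard_normal(n)
        female = rng.random(n) < 0.5
        logit = -0.5 + 0.8 * x - 0.4 * female
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        df = pd.DataFrame({"y": y, "x": x, "female": female})
        fit = fit_logistic(df, "y", ["x", "female"])
        for term, beta in (("x", 0.8), ("female", -0.4)):
            row = fit.term(term)
            assert row["ci_low"] <= np.exp(beta) <= row["ci_high"]

    def test_wald_ci_brackets_or_and_is_log_symmetric(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"y": rng.random(500) < 0.4,
                           "x": rng.standard_normal(500)})
        fit = fit_logistic(df, "y", ["x"])
        for _, row in fit.table.iterrows():
            assert row["ci_low"] < row["odds_ratio"] < row["ci_high"]
            assert row["ci_low"] * row["ci_high"] == pytest.approx(
                row["odds_ratio"] ** 2, rel=1e-9)
            assert row["odds_ratio"] > 0

    def test_perfect_separation_reported(self):
        df = pd.DataFrame({"y": [0.0] * 20 + [1.0] * 20,
                           "x": [0.0] * 20 + [1.0] * 20})
        with pytest.raises(SeparationError):
            fit_logistic(df, "y", ["x"])

    def test_factor_reference_levels(self):
        rng = np.random.default_rng(12)
        cls = rng.choice(["robust", "pre_frail", "frail"], 3000, p=[0.2, 0.4, 0.4])
        y = rng.random(3000) < np.where(cls == "frail", 0.5, 0.25)
        df = pd.DataFrame({"y": y, "frailty_class": cls})
        fit = fit_logistic(df, "y", ["frailty_class"],
                           reference_levels={"frailty_class": "robust"})
        names = set(fit.table["term"])
        assert "frailty_class[frail]" in names
        assert "frailty_class[robust]" not in names

    def test_complete_case_n_reported(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"y": (rng.random(300) < 0.5).astype(float),
                           "x": rng.standard_normal(300)})
        df.loc[:49, "x"] = np.nan
        assert fit_logistic(df, "y", ["x"]).n == 250


class TestMultinomial:
    def test_reference_level_absent_and_or_positive(self):
        rng = np.random.default_rng(14)
        n = 4000
        x = rng.standard_normal(n)
        # planted: frail log-odds (vs robust) increase with x
        lin_pre = 0.5 + 0.2 * x
        lin_frail = 0.5 + 0.9 * x
        denom = 1 + np.exp(lin_pre) + np.exp(lin_frail)
        u = rng.random(n)
        p_rob = 1 / denom
        p_pre = np.exp(lin_pre) / denom
        cls = np.where(u < p_rob, "robust",
                       np.where(u < p_rob + p_pre, "pre_frail", "frail"))
        df = pd.DataFrame({"cls": cls, "x": x})
        out = fit_multinomial(df, "cls", ["x"], outcome_reference="robust")
        assert set(out["outcome_level"]) == {"pre_frail", "frail"}
        row = out[(out["outcome_level"] == "frail") & (out["term"] == "x")].iloc[0]
        assert row["ci_low"] <= np.exp(0.9) <= row["ci_high"]


class TestUShape:
    def test_constant_fi_gives_flat_profile(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame({"sbp": rng.uniform(100, 180, 2000), "fi": 0.2})
        prof = ushape_profile(df, "sbp", 10.0)
        assert np.allclose(prof.mean_fi[prof.n > 0], 0.2)

    def test_hand_built_fixture_exact_bin_means(self):
        df = pd.DataFrame({
            "sbp": [102.0, 104.0, 111.0, 112.0, 113.0, 125.0],
            "fi": [0.10, 0.20, 0.30, 0.30, 0.60, 0.50],
        })
        prof = ushape_profile(df, "sbp", 10.0, min_n=1)
        assert list(prof.edges) == [100.0, 110.0, 120.0, 130.0]
        assert prof.mean_fi[0] == pytest.approx(0.15)
        assert prof.mean_fi[1] == pytest.approx(0.40)
        assert prof.mean_fi[2] == pytest.approx(0.50)
        assert list(prof.n) == [2, 3, 1]

    def test_low_n_bins_flagged_and_skipped(self):
        rng = np.random.default_rng(16)
        sbp = np.concatenate([rng.uniform(120, 150, 500), [250.0]])
        fi = np.concatenate([rng.uniform(0.1, 0.3, 500), [0.0]])
        prof = ushape_profile(pd.DataFrame({"sbp": sbp, "fi": fi}), "sbp", 10.0)
        assert prof.low_n_flag[-1]
        assert prof.argmin_bin() != len(prof.n) - 1

    def test_empty_cohort_error(self):
        with pytest.raises(ValueError):
            ushape_profile(pd.DataFrame({"sbp": [], "fi": []}), "sbp", 10.0)
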