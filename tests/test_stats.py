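"""Statistics layer vs independent oracles (brute force, pingouin, sklearn)."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from ecitt import (
    age_trend,
    cohens_kappa,
    correlate,
    cronbach_alpha,
    get_profile,
    inhibitory_item_matrix,
    mixed_anova,
    paired_d_from_t,
    paired_t,
    partial_correlate,
    rm_anova,
    score_session,
    scores_frame,
    simulate_cohort,
    welch_t,
    welch_t_from_stats,
)

HAND_MATRIX = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]])


class TestAlpha:
    def test_identical_varying_columns_give_alpha_one(self):
        col = np.array([1, 0, 1, 1, 0])
        m = np.column_stack([col, col, col])
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_hand_matrix_matches_covariance_form_oracle(self):
        # alpha = k/(k-1) * (1 - trace(C)/sum(C)) with sample covariance C
        C = np.cov(HAND_MATRIX, rowvar=False, ddof=1)
        k = HAND_MATRIX.shape[1]
        oracle = k / (k - 1) * (1.0 - np.trace(C) / C.sum())
        assert cronbach_alpha(HAND_MATRIX) == pytest.approx(oracle)

    def test_independent_items_give_near_zero_alpha(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 2, size=(5000, 8))
        assert abs(cronbach_alpha(m)) < 0.05

    def test_alpha_invariant_to_item_relabeling(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 2, size=(30, 8))
        perm = rng.permutation(8)
        assert cronbach_alpha(m) == pytest.approx(cronbach_alpha(m[:, perm]))

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(2)
        latent = rng.normal(size=(40, 1))
        m = (latent + rng.normal(size=(40, 6)) > 0).astype(int)
        expected = pg.cronbach_alpha(data=pd.DataFrame(m))[0]
        assert cronbach_alpha(m) == pytest.approx(expected, abs=1e-10)

    def test_zero_total_variance_raises(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((4, 3)))

    def test_item_matrix_keeps_only_complete_participants(self):
        members = simulate_cohort([get_profile("toddler_24m")], 40, seed=0)
        sessions = [m.session for m in members]
        m8 = inhibitory_item_matrix(sessions, k=8)
        m6 = inhibitory_item_matrix(sessions, k=6)
        assert m8.shape[1] == 8 and m6.shape[1] == 6
        assert m6.shape[0] >= m8.shape[0]  # 6-item fallback keeps more children
        assert set(np.unique(m6)) <= {0, 1}


class TestKappa:
    def test_identical_raters_give_one(self):
        labels = ["valid", "invalid", "valid", "valid"]
        assert cohens_kappa(labels, labels) == pytest.approx(1.0)

    def test_hand_2x2_table(self):
        # table: a=20 both yes, b=5, c=10, d=15 -> po=0.7
        r1 = ["y"] * 25 + ["n"] * 25
        r2 = ["y"] * 20 + ["n"] * 5 + ["y"] * 10 + ["n"] * 15
        p_o = 35 / 50
        p_e = (25 / 50) * (30 / 50) + (25 / 50) * (20 / 50)
        oracle = (p_o - p_e) / (1 - p_e)
        assert cohens_kappa(r1, r2) == pytest.approx(oracle)

    def test_symmetry_and_sklearn_agreement(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        r1 = rng.integers(0, 3, size=500)
        r2 = np.where(rng.random(500) < 0.7, r1, rng.integers(0, 3, size=500))
        k12 = cohens_kappa(r1, r2)
        assert k12 == pytest.approx(cohens_kappa(r2, r1))
        assert k12 == pytest.approx(cohen_kappa_score(r1, r2), abs=1e-12)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(4)
        assert abs(cohens_kappa(rng.integers(0, 2, 20000),
                                rng.integers(0, 2, 20000))) < 0.03

    def test_degenerate_single_category_raises(self):
        with pytest.raises(ValueError):
            cohens_kappa(["a", "a"], ["a", "a"])


class TestTTests:
    def test_identical_groups_give_zero(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.d == 0.0

    def test_pooled_d_from_printed_group_summaries(self):
        res = welch_t_from_stats(19.29, 29.72, 36, 5.37, 10.64, 41)
        assert res.d == pytest.approx(0.64, abs=0.005)
        assert res.t > 2 and res.p < 0.05

    def test_paired_d_convention(self):
        assert paired_d_from_t(3.78, 19) == pytest.approx(0.87, abs=0.005)
        rng = np.random.default_rng(5)
        x = rng.normal(10, 2, 25)
        y = x + rng.normal(0.5, 1, 25)
        res = paired_t(x, y)
        assert res.d == pytest.approx(res.t / np.sqrt(25))

    def test_paired_t_reduces_to_one_sample_t_on_differences(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        oracle = sps.ttest_1samp(x - y, 0.0)
        res = paired_t(x, y)
        assert res.t == pytest.approx(oracle.statistic)
        assert res.p == pytest.approx(oracle.pvalue)

    def test_welch_equals_student_under_equal_variance_and_n(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.4, 1, 20)
        # force exactly equal sample variances by standardising both groups
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1) + 0.4
        welch = welch_t(x, y)
        student = sps.ttest_ind(x, y, equal_var=True)
        assert welch.t == pytest.approx(student.statistic)
        assert welch.df == pytest.approx(38.0)

    def test_raw_welch_matches_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 15)
        y = rng.normal(1, 3, 40)
        res = welch_t(x, y)
        oracle = sps.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(oracle.statistic)
        assert res.p == pytest.approx(oracle.pvalue)
        assert res.df == pytest.approx(oracle.df)


def _long_mixed_data(seed=0, n_per_group=8, group_effect=0.0, cond_effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for gi, g in enumerate(("young", "old")):
        for s in range(n_per_group):
            subj = f"{g}{s}"
            base = rng.normal(10.0 + gi * group_effect, 1.0)
            for ci, cond in enumerate(("prepotent", "inhibitory")):
                rows.append({"subject": subj, "group": g, "condition": cond,
                             "score": base + ci * cond_effect + rng.normal(0, 0.5)})
    return pd.DataFrame(rows)


class TestAnova:
    def test_null_data_gives_small_f(self):
        data = _long_mixed_data(seed=1)
        table = mixed_anova(data, dv="score", subject="subject",
                            within="condition", between="group")
        assert (table["p"] > 0.01).all()  # no true effects present

    def test_ss_decomposition_matches_brute_force_oracle(self):
        data = _long_mixed_data(seed=2, group_effect=1.0, cond_effect=0.8)
        table = mixed_anova(data, dv="score", subject="subject",
                            within="condition", between="group")
        # brute-force cell-mean sums of squares
        wide = data.pivot_table(index="subject", columns="condition", values="score")
        groups = data.drop_duplicates("subject").set_index("subject")["group"]
        Y = wide.to_numpy()
        g = groups.loc[wide.index].to_numpy()
        grand = Y.mean()
        ss_total = ((Y - grand) ** 2).sum()
        ss_A = sum((g == lvl).sum() * 2 * (Y[g == lvl].mean() - grand) ** 2
                   for lvl in ("young", "old"))
        ss_subj = 2 * ((Y.mean(axis=1) - grand) ** 2).sum() - ss_A
        ss_B = Y.shape[0] * ((Y.mean(axis=0) - grand) ** 2).sum()
        ss_AB = sum(
            (g == lvl).sum()
            * ((Y[g == lvl].mean(axis=0) - Y[g == lvl].mean()
                - Y.mean(axis=0) + grand) ** 2).sum()
            for lvl in ("young", "old")
        )
        ss_err = ss_total - ss_A - ss_subj - ss_B - ss_AB
        n_s, a = Y.shape[0], 2
        f_A = (ss_A / 1) / (ss_subj / (n_s - a))
        f_B = (ss_B / 1) / (ss_err / (n_s - a))
        f_AB = (ss_AB / 1) / (ss_err / (n_s - a))
        assert table.loc["group", "F"] == pytest.approx(f_A)
        assert table.loc["condition", "F"] == pytest.approx(f_B)
        assert table.loc["group * condition", "F"] == pytest.approx(f_AB)
        assert table.loc["group", "np2"] == pytest.approx(ss_A / (ss_A + ss_subj))

    def test_matches_pingouin_mixed_anova(self):
        import pingouin as pg

        data = _long_mixed_data(seed=3, group_effect=0.7, cond_effect=0.5)
        ours = mixed_anova(data, dv="score", subject="subject",
                           within="condition", between="group")
        theirs = pg.mixed_anova(data=data, dv="score", within="condition",
                                subject="subject", between="group").set_index("Source")
        assert ours.loc["group", "F"] == pytest.approx(theirs.loc["group", "F"])
        assert ours.loc["condition", "F"] == pytest.approx(theirs.loc["condition", "F"])
        assert ours.loc["group * condition", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"]
        )
        assert ours.loc["condition", "np2"] == pytest.approx(
            theirs.loc["condition", "np2"]
        )

    def test_between_only_effect_equals_t_squared(self):
        data = _long_mixed_data(seed=4, group_effect=1.5, cond_effect=0.0)
        table = mixed_anova(data, dv="score", subject="subject",
                            within="condition", between="group")
        subj_means = data.groupby(["subject", "group"])["score"].mean().reset_index()
        x = subj_means.loc[subj_means["group"] == "young", "score"]
        y = subj_means.loc[subj_means["group"] == "old", "score"]
        t = sps.ttest_ind(x, y, equal_var=True).statistic
        assert table.loc["group", "F"] == pytest.approx(t**2)

    def test_two_way_within_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(9)
        rows = []
        for s in range(10):
            base = rng.normal(0, 1)
            for ai, age in enumerate(("18m", "21m", "24m")):
                for ci, cond in enumerate(("prepotent", "inhibitory")):
                    rows.append({"subject": s, "age": age, "condition": cond,
                                 "score": base + 0.5 * ai + 0.8 * ci
                                 + rng.normal(0, 0.6)})
        data = pd.DataFrame(rows)
        ours = rm_anova(data, dv="score", subject="subject",
                        within=["condition", "age"])
        theirs = pg.rm_anova(data=data, dv="score", subject="subject",
                             within=["condition", "age"], detailed=True)
        theirs = theirs.set_index("Source")
        assert ours.loc["condition", "F"] == pytest.approx(theirs.loc["condition", "F"])
        assert ours.loc["age", "F"] == pytest.approx(theirs.loc["age", "F"])
        assert ours.loc["condition * age", "F"] == pytest.approx(
            theirs.loc["condition * age", "F"]
        )

    def test_incomplete_subjects_are_dropped_listwise(self):
        data = _long_mixed_data(seed=10, cond_effect=1.0)
        data = data.drop(data[(data["subject"] == "young0")
                              & (data["condition"] == "inhibitory")].index)
        full = mixed_anova(data[data["subject"] != "young0"], dv="score",
                           subject="subject", within="condition", between="group")
        dropped = mixed_anova(data, dv="score", subject="subject",
                              within="condition", between="group")
        pd.testing.assert_frame_equal(full, dropped)


class TestCorrelation:
    def test_perfect_correlation_degenerate_ci(self):
        x = np.arange(10.0)
        res = correlate(x, x, b_resamples=200, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0) and res.ci_high == pytest.approx(1.0)

    def test_bootstrap_ci_is_seed_reproducible(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        a = correlate(x, y, b_resamples=500, seed=3)
        b = correlate(x, y, b_resamples=500, seed=3)
        c = correlate(x, y, b_resamples=500, seed=4)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)
        assert a.ci_low < a.r < a.ci_high

    def test_bootstrap_ci_coverage_near_nominal(self):
        """Percentile-bootstrap coverage on bivariate normal data (scaled down)."""
        rho = 0.5
        n, reps = 40, 300
        rng = np.random.default_rng(12)
        cov = [[1.0, rho], [rho, 1.0]]
        hits = 0
        for i in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            res = correlate(xy[:, 0], xy[:, 1], b_resamples=400, seed=i)
            hits += res.ci_low <= rho <= res.ci_high
        # percentile bootstrap is known to slightly undercover at this n
        assert 0.88 <= hits / reps <= 0.99

    def test_partial_r_unaffected_by_irrelevant_control(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=200)
        y = 0.6 * x + rng.normal(size=200)
        z = rng.normal(size=200)  # unrelated to both
        raw = correlate(x, y, b_resamples=100, seed=0)
        part = partial_correlate(x, y, z, b_resamples=100, seed=0)
        assert part.r == pytest.approx(raw.r, abs=0.03)

    def test_partial_r_matches_recursive_formula_oracle(self):
        x = np.array([3.0, 5.0, 2.0, 8.0, 7.0, 1.0, 4.0, 6.0, 9.0, 2.5])
        y = np.array([2.0, 4.5, 2.5, 7.0, 8.0, 1.5, 3.0, 5.0, 8.5, 3.5])
        z = np.array([1.0, 2.0, 1.5, 4.0, 3.5, 0.5, 2.5, 3.0, 4.5, 1.0])
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        oracle = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        res = partial_correlate(x, y, z, b_resamples=100, seed=0)
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAgeTrend:
    def test_exactly_linear_data_has_no_quadratic_increment(self):
        age = np.linspace(18, 84, 30)
        score = 2.0 - 0.01 * age
        res = age_trend(age, score)
        assert res.delta_r2 == pytest.approx(0.0, abs=1e-10)

    def test_u_shape_recovered_with_coefficients_from_normal_equations(self):
        rng = np.random.default_rng(14)
        age = np.linspace(48, 1000, 120)  # 4 to ~84 years, in months
        a_c = age - age.mean()
        score = 5.0 - 0.02 * a_c + 4e-5 * a_c**2 + rng.normal(0, 0.5, age.size)
        res = age_trend(age, score)
        assert res.p_increment < 0.01 and res.delta_r2 > 0.1
        X = np.column_stack([np.ones_like(a_c), a_c, a_c**2])
        oracle = np.linalg.solve(X.T @ X, X.T @ score)
        assert np.allclose(res.quadratic_coefs, oracle, atol=1e-8)

    def test_toddler_cohort_shows_negative_linear_age_slope(self):
        profiles = [get_profile(lbl) for lbl in
                    ("toddler_18m", "toddler_21m", "toddler_24m", "toddler_30m")]
        members = simulate_cohort(profiles, 60, seed=15)
        fr = scores_frame([score_session(m.session) for m in members])
        fr = fr[fr["included"]]
        res = age_trend(fr["age_months"], fr["accd"])
        assert res.linear_coefs[1] < 0 and res.linear_p < 0.01

    def test_degenerate_ages_raise(self):
        with pytest.raises(ValueError):
            age_trend([24.0, 24.0, 30.0, 30.0], [1.0, 2.0, 3.0, 4.0])
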