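"""Cluster-robust linear models, Scheffe contrasts, marginal means,
ANOVA, regression, tumour volume."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from dcequant import (anova_bonferroni, fit_clustered_lm, marginal_means,
                      ols_association, scheffe_contrasts, tumour_volume)
from dcequant.cohort_stats import contrast_ci
from dcequant.phantom import CohortSpec, GROUPS, generate_cohort


def simple_table(seed=0, n_per_group=4, effect=None):
    return generate_cohort(CohortSpec(
        seed=seed, n_per_group=n_per_group,
        group_ve_means=effect or {g: 0.30 for g in GROUPS}))


class TestClusteredLM:
    def test_matches_statsmodels_cluster_covariance(self):
        """Independent cross-check of the CR1 sandwich against
        statsmodels' clustered OLS."""
        smf = pytest.importorskip("statsmodels.formula.api")
        tab = simple_table(seed=9)
        ours = fit_clustered_lm(tab, "ve", cov_type="CR1",
                                df_rule="clusters")
        ref = smf.ols("ve ~ C(group) + C(timepoint)", data=tab).fit(
            cov_type="cluster", cov_kwds={"groups": tab["animal_id"]})
        np.testing.assert_allclose(ours.params, ref.params.values,
                                   rtol=1e-10)
        np.testing.assert_allclose(np.sqrt(np.diag(ours.cov)),
                                   ref.bse.values, rtol=1e-10)

    def test_duplicating_rows_keeps_coefficients(self):
        tab = simple_table(seed=1)
        doubled = pd.concat([tab, tab], ignore_index=True)
        a = fit_clustered_lm(tab, "ve")
        b = fit_clustered_lm(doubled, "ve")
        np.testing.assert_allclose(a.params, b.params, rtol=1e-10)

    def test_cluster_relabelling_and_row_order_invariance(self):
        tab = simple_table(seed=2)
        shuffled = tab.sample(frac=1.0, random_state=4).reset_index(drop=True)
        relabel = {a: f"x{i}" for i, a in enumerate(tab.animal_id.unique())}
        shuffled["animal_id"] = shuffled["animal_id"].map(relabel)
        a = fit_clustered_lm(tab, "ve")
        b = fit_clustered_lm(shuffled, "ve")
        np.testing.assert_allclose(np.sqrt(np.diag(a.cov)),
                                   np.sqrt(np.diag(b.cov)), rtol=1e-10)

    def test_robust_close_to_classical_when_iid(self):
        """One observation per cluster, homoscedastic errors, large N:
        robust SEs within 10% of classical OLS SEs."""
        rng = np.random.default_rng(0)
        n = 2000
        g = rng.choice(list("abcd"), n)
        y = 1.0 + (g == "b") * 0.5 + rng.normal(0, 1.0, n)
        tab = pd.DataFrame(dict(animal_id=np.arange(n), group=g,
                                timepoint="t1", ve=y))
        m = fit_clustered_lm(tab, "ve", cov_type="CR1", df_rule="clusters")
        X = m._X
        sigma2 = np.sum((m._X @ m.params - tab.ve.values) ** 2) / (n - 4)
        classical = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        robust = np.sqrt(np.diag(m.cov))
        assert np.all(np.abs(robust / classical - 1) < 0.10)

    def test_qc_failed_rows_excluded(self):
        tab = simple_table(seed=3)
        tab2 = tab.copy()
        spoiled = tab2.index[:4]
        tab2.loc[spoiled, "ve"] = 5.0
        tab2.loc[spoiled, "qc_pass"] = False
        clean = fit_clustered_lm(tab.drop(index=spoiled), "ve")
        flagged = fit_clustered_lm(tab2, "ve")
        np.testing.assert_allclose(clean.params, flagged.params)

    def test_too_few_clusters_rejected(self):
        tab = pd.DataFrame(dict(animal_id=["a"] * 4,
                                group=["g1", "g1", "g2", "g2"],
                                timepoint=["t"] * 4, ve=[1, 2, 3, 4.0]))
        with pytest.raises(ValueError):
            fit_clustered_lm(tab, "ve")


class TestScheffe:
    def test_adjusted_p_at_least_raw_p(self):
        tab = simple_table(seed=5, effect={
            "control": 0.3, "mAb": 0.32, "NK": 0.25, "NK+mAb": 0.42})
        m = fit_clustered_lm(tab, "ve")
        for c in scheffe_contrasts(m):
            raw = 2 * stats.t.sf(abs(c.t), m.df_denom)
            assert c.p_adjusted >= raw - 1e-12

    def test_p_tends_to_one_as_t_tends_to_zero(self):
        tab = simple_table(seed=6, n_per_group=6)
        m = fit_clustered_lm(tab, "ve")
        dim = m.n_groups - 1
        for t in (1.0, 0.3, 0.1, 0.01):
            p = stats.f.sf(t ** 2 / dim, dim, m.df_denom)
            assert p < stats.f.sf((t / 10) ** 2 / dim, dim, m.df_denom)
        assert stats.f.sf(0.0, dim, m.df_denom) == 1.0

    def test_adjusted_p_matches_f_tail_integration(self):
        """g = 4, df = 10, t = 3.0: adjusted p equals the numerically
        integrated F(3, 10) upper tail at F* = 3.0."""
        t, g, df = 3.0, 4, 10
        f_star = t ** 2 / (g - 1)
        oracle, _ = quad(lambda x: stats.f.pdf(x, g - 1, df), f_star,
                         np.inf, limit=200)
        assert stats.f.sf(f_star, g - 1, df) == pytest.approx(oracle,
                                                              rel=1e-8)
        # and the package's contrast p uses exactly this tail
        tab = simple_table(seed=7)
        m = fit_clustered_lm(tab, "ve", df_rule="clusters")
        c = scheffe_contrasts(m, pairs=[("NK", "control")])[0]
        expect = stats.f.sf(c.t ** 2 / 3, 3, m.df_denom)
        assert c.p_adjusted == pytest.approx(expect, rel=1e-12)

    def test_monotone_decreasing_in_abs_t(self):
        dim, df = 3, 12
        ts = [0.5, 1.0, 2.0, 3.0, 5.0]
        ps = [stats.f.sf(t ** 2 / dim, dim, df) for t in ts]
        assert np.all(np.diff(ps) < 0)

    def test_simultaneous_ci_contains_estimate(self):
        tab = simple_table(seed=8)
        m = fit_clustered_lm(tab, "ve")
        for c in scheffe_contrasts(m):
            assert c.ci_lower <= c.estimate <= c.ci_upper

    def test_nonestimable_contrast_rejected(self):
        m = fit_clustered_lm(simple_table(seed=9), "ve")
        with pytest.raises(ValueError):
            scheffe_contrasts(m, pairs=[("NK", "placebo")])

    def test_power_increases_with_animals_per_group(self):
        """Default effect pattern: the NK+mAb-vs-NK rejection rate rises
        monotonically with group size."""
        rates = []
        for n in (3, 5, 8):
            hits = 0
            for i in range(60):
                tab = generate_cohort(CohortSpec(seed=40000 + i,
                                                 n_per_group=n))
                m = fit_clustered_lm(tab, "ve")
                c = scheffe_contrasts(m, pairs=[("NK+mAb", "NK")])[0]
                hits += (c.estimate > 0) and (c.p_adjusted < 0.05)
            rates.append(hits / 60)
        assert rates[0] <= rates[1] <= rates[2]


class TestMarginalMeans:
    def test_balanced_saturated_design_equals_cell_means(self):
        tab = simple_table(seed=10)
        m = fit_clustered_lm(tab, "ve", interaction=True)
        mm = marginal_means(m)
        for _, row in mm.iterrows():
            sel = (tab.group == row.group) & (tab.timepoint == row.timepoint)
            assert row["mean"] == pytest.approx(tab.loc[sel, "ve"].mean())

    def test_shift_equivariance(self):
        tab = simple_table(seed=11)
        shifted = tab.assign(ve=tab.ve + 0.123)
        a = marginal_means(fit_clustered_lm(tab, "ve"))
        b = marginal_means(fit_clustered_lm(shifted, "ve"))
        np.testing.assert_allclose(b["mean"], a["mean"] + 0.123, rtol=1e-10)

    def test_unbalanced_design_matches_hand_computed_combination(self):
        tab = simple_table(seed=12).iloc[3:].reset_index(drop=True)
        m = fit_clustered_lm(tab, "ve")
        mm = marginal_means(m, by="group")
        # hand-build the marginal design row for one group
        g = m.group_levels[1]
        L = np.zeros(len(m.column_names))
        L[0] = 1.0
        L[m.column_names.index(f"group[{g}]")] = 1.0
        for tp in m.timepoint_levels[1:]:
            L[m.column_names.index(f"timepoint[{tp}]")] = \
                1.0 / len(m.timepoint_levels)
        expect = L @ m.params
        got = mm.loc[mm.group == g, "mean"].iloc[0]
        assert got == pytest.approx(expect, rel=1e-12)


class TestOLSAssociation:
    def test_exact_line_r2_one(self):
        x = np.arange(10.0)
        res = ols_association(x, 2.0 - 0.5 * x)
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(-0.5)

    def test_independent_noise_r2_near_zero(self):
        rng = np.random.default_rng(1)
        res = ols_association(rng.normal(size=5000), rng.normal(size=5000))
        assert res["r_squared"] < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ols_association(np.ones(5), np.arange(5.0))


class TestANOVA:
    def test_identical_groups_zero_f(self):
        tab = pd.DataFrame(dict(group=list("aabb"), ki67=[0.4, 0.4, 0.4,
                                                          0.4]))
        res = anova_bonferroni(tab, "ki67")
        assert res["F"] == pytest.approx(0.0, abs=1e-12) or np.isnan(
            res["F"])

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame(dict(
            group=np.repeat(["a", "b"], 8),
            ki67=np.r_[rng.normal(0.4, 0.05, 8), rng.normal(0.5, 0.05, 8)]))
        res = anova_bonferroni(tab, "ki67")
        t = res["pairwise"].t.iloc[0]
        assert res["F"] == pytest.approx(t ** 2, rel=1e-10)

    def test_f_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(4)
        vals = {g: rng.normal(m, 0.05, 6) for g, m in
                zip("abc", (0.3, 0.4, 0.35))}
        tab = pd.DataFrame(dict(
            group=np.repeat(list(vals), 6),
            ki67=np.concatenate([vals[g] for g in vals])))
        res = anova_bonferroni(tab, "ki67")
        grand = tab.ki67.mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2
                         for v in vals.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in vals.values())
        f_oracle = (ss_between / 2) / (ss_within / (18 - 3))
        assert res["F"] == pytest.approx(f_oracle, rel=1e-10)

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(5)
        tab = pd.DataFrame(dict(group=np.repeat(list("abcd"), 5),
                                ki67=rng.normal(0.4, 0.05, 20)))
        res = anova_bonferroni(tab, "ki67")
        assert (res["pairwise"].p_adj <= 1.0).all()

    def test_degenerate_groups_rejected(self):
        tab = pd.DataFrame(dict(group=["a", "a", "b"], ki67=[1, 2, 3.0]))
        with pytest.raises(ValueError):
            anova_bonferroni(tab, "ki67")


class TestTumourVolume:
    def test_plain_count(self):
        roi = np.zeros((5, 5, 2), bool)
        roi[1:3, 1:4, 0] = True
        assert tumour_volume(roi) == 6

    def test_zero_enhancement_factor_is_noop(self):
        roi = np.ones((3, 3, 1), bool)
        pre = np.ones((3, 3, 1))
        post = np.ones((3, 3, 1)) * 1.5
        assert tumour_volume(roi, post=post, pre=pre,
                             enhancement_factor=0.0) == 9

    def test_enhancement_threshold_refinement(self):
        roi = np.ones((4, 4, 1), bool)
        pre = np.ones((4, 4, 1))
        post = np.ones((4, 4, 1))
        post[:2] = 2.0
        assert tumour_volume(roi, post=post, pre=pre,
                             enhancement_factor=1.5) == 8

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            tumour_volume(np.zeros((3, 3, 1), bool))

    def test_sphere_count_matches_analytic_volume(self):
        """Voxel count of a rasterised sphere within one voxel-shell of
        4/3 pi r^3."""
        r = 10.0
        grid = np.indices((31, 31, 31)).astype(float) - 15.0
        sphere = (grid ** 2).sum(axis=0) <= r ** 2
        count = tumour_volume(sphere)
        analytic = 4.0 / 3.0 * np.pi * r ** 3
        shell = 4.0 * np.pi * r ** 2  # one-voxel-thick shell volume
        assert abs(count - analytic) <= shell
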