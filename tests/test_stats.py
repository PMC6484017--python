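"""Statistical battery: oracles, closed forms and cross-checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chewmix import stats as cs
from chewmix.synth import CohortSpec, generate_cohort

from conftest import make_cohort


class TestDescriptives:
    def test_single_row_cohort(self):
        coh = make_cohort([1]).iloc[:3]
        coh = coh.assign(session=[1, 2, 3])
        d = cs.descriptives(coh)
        row = d[(d.cgc == 0) & (d.session == 1)].iloc[0]
        assert row["vhh_min"] == row["vhh_max"] == row["vhh_mean"]
        assert row["vhh_sd"] == 0.0

    def test_noise_free_cells_equal_linear_predictor(self):
        spec = CohortSpec(n_subjects=40, subject_sd=0.0, residual_sd=0.0, seed=9)
        coh = generate_cohort(spec)
        d = cs.descriptives(coh)
        beta_s = {1: 0.0, 2: spec.session_effects[0], 3: spec.session_effects[1]}
        beta_c = {0: 0.0, 1: spec.cgc_effects[0], 2: spec.cgc_effects[1]}
        for row in d.itertuples():
            if row.n == 0:
                continue
            cell = coh[(coh.cgc == row.cgc) & (coh.session == row.session)]
            mu = (spec.baseline_vhh + beta_c[row.cgc] + beta_s[row.session]
                  + spec.age_slope * cell["age"].mean())
            assert row.vhh_mean == pytest.approx(mu, rel=1e-12)

    def test_cell_counts_sum_to_subjects(self, small_cohort):
        d = cs.descriptives(small_cohort)
        n_subj = small_cohort["subject_id"].nunique()
        assert d[d.session == 1]["n"].sum() == n_subj


class TestPairedT:
    def test_identical_vectors_give_p_one(self):
        x = np.arange(10.0)
        assert cs.paired_t(x, x.copy()) == (0.0, 1.0)

    def test_constant_nonzero_difference_is_degenerate(self):
        t, p = cs.paired_t(np.array([2.0, 3, 4, 5]), np.array([1.0, 2, 3, 4]))
        assert np.isinf(t) and p == 0.0

    def test_zero_mean_difference(self):
        t, p = cs.paired_t([1.0, 2, 3], [3.0, 2, 1])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert cs.paired_t(x, y) == pytest.approx(sps.ttest_rel(x, y))


class TestEtaSquared:
    def test_identical_group_means_give_zero(self):
        v = np.tile([1.0, 2.0, 3.0], 3)
        g = np.repeat([0, 1, 2], 3)
        assert cs.eta_squared(v, g) == pytest.approx(0.0, abs=1e-12)

    def test_distinct_constant_groups_give_one(self):
        v = np.repeat([1.0, 5.0, 9.0], 4)
        g = np.repeat([0, 1, 2], 4)
        assert cs.eta_squared(v, g) == pytest.approx(1.0)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            cs.eta_squared([1.0, 2.0], [0, 0])

    def test_matches_anova_decomposition(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=60)
        g = rng.integers(0, 3, size=60)
        v[g == 2] += 1.0
        f, _ = sps.f_oneway(*(v[g == k] for k in range(3)))
        # eta^2 = (F*df1) / (F*df1 + df2)
        df1, df2 = 2, 57
        assert cs.eta_squared(v, g) == pytest.approx(f * df1 / (f * df1 + df2))

    def test_null_association_when_cgc_independent_of_age(self):
        """Equal CGC weights across age groups leave eta^2 near zero."""
        flat = ((1 / 3, 1 / 3, 1 / 3),) * 4
        vals = []
        for seed in range(50):
            coh = generate_cohort(CohortSpec(n_subjects=265, cgc_given_age=flat,
                                             seed=seed))
            subj = coh.drop_duplicates("subject_id")
            vals.append(cs.eta_squared(subj["age"], subj["cgc"]))
        assert np.mean(vals) < 0.05


class TestNormalityBattery:
    def test_null_acceptance_rate(self):
        rng = np.random.default_rng(3)
        ok_ks = ok_sw = 0
        for _ in range(100):
            coh = pd.DataFrame({
                "vhh": rng.normal(0, 1, 200), "cgc": 0,
                "dental_status": "natural", "sex": "female",
            })
            row = cs.normality_battery(coh).iloc[0]
            ok_ks += row["ks_p"] > 0.05
            ok_sw += row["sw_p"] > 0.05
        assert ok_ks >= 90 and ok_sw >= 90

    def test_bimodal_mixture_is_rejected(self):
        rng = np.random.default_rng(4)
        v = np.concatenate([rng.normal(0, 1, 100), rng.normal(6, 1, 100)])
        row = cs.normality_battery(pd.DataFrame({"vhh": v})).iloc[0]
        assert row["sw_p"] < 0.001

    def test_constant_group_is_flagged(self):
        row = cs.normality_battery(pd.DataFrame({"vhh": np.ones(10)})).iloc[0]
        assert "degenerate" in row["note"]


class TestMauchly:
    def test_compound_symmetry_gives_epsilon_one(self):
        coh = make_cohort([500], subject_sd=2.0, noise_sd=1.0, seed=5)
        sph = cs.mauchly(coh)
        assert sph.eps_gg == pytest.approx(1.0, abs=0.02)
        assert sph.p > 0.05

    def test_lower_bound_epsilon(self, small_cohort):
        assert cs.mauchly(small_cohort).eps_lower == 0.5

    def test_single_group_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        coh = make_cohort([40], within_corr=[[1, .5, .2], [.5, 1, .5], [.2, .5, 1]],
                          seed=6)
        sph = cs.mauchly(coh)
        long = coh.rename(columns={"vhh": "dv"})
        ref = pg.sphericity(long, dv="dv", subject="subject_id", within="session")
        assert sph.W == pytest.approx(ref.W, rel=1e-10)
        assert sph.chi2 == pytest.approx(ref.chi2, rel=1e-10)
        assert sph.p == pytest.approx(ref.pval, rel=1e-10)
        for corr, ours in (("gg", sph.eps_gg), ("hf", sph.eps_hf)):
            ref_eps = pg.epsilon(long, dv="dv", subject="subject_id",
                                 within="session", correction=corr)
            assert ours == pytest.approx(ref_eps, rel=1e-10)

    def test_epsilon_ordering(self, small_cohort):
        sph = cs.mauchly(small_cohort)
        assert 0.5 <= sph.eps_gg <= sph.eps_hf <= 1.0


def _brute_force_split_plot(coh):
    """Balanced split-plot sums of squares from the cell-means formulas."""
    y = coh.pivot(index="subject_id", columns="session", values="vhh").to_numpy()
    g = (coh.drop_duplicates("subject_id").set_index("subject_id")
         .loc[coh.pivot(index="subject_id", columns="session", values="vhh").index,
              "cgc"].to_numpy())
    levels = np.unique(g)
    n = (g == levels[0]).sum()
    k = y.shape[1]
    grand = y.mean()
    cell = np.stack([y[g == lv].mean(axis=0) for lv in levels])  # (g, k)
    grp = cell.mean(axis=1)
    ses = cell.mean(axis=0)
    subj = y.mean(axis=1)

    ss_session = n * len(levels) * ((ses - grand) ** 2).sum()
    ss_inter = n * ((cell - grp[:, None] - ses[None, :] + grand) ** 2).sum()
    ss_err_w = sum(((y[g == lv] - cell[i][None, :]
                     - (subj[g == lv] - grp[i])[:, None]) ** 2).sum()
                   for i, lv in enumerate(levels))
    ss_cgc = n * k * ((grp - grand) ** 2).sum()
    ss_err_b = k * sum(((subj[g == lv] - grp[i]) ** 2).sum()
                       for i, lv in enumerate(levels))
    return ss_session, ss_inter, ss_err_w, ss_cgc, ss_err_b


class TestMixedAnova:
    def test_matches_brute_force_on_small_balanced_cohorts(self):
        """SS decomposition equals the cell-means oracle to 1e-8 relative."""
        for seed in range(50):
            coh = make_cohort([4, 4, 4], seed=seed,
                              group_effects=(0.0, 0.5, 1.0),
                              session_effects=(0.0, 0.3, 0.6))
            res = cs.mixed_anova(coh, correction="none")
            oracle = _brute_force_split_plot(coh)
            got = [res.within.loc[0, "SS"], res.within.loc[1, "SS"],
                   res.within.loc[2, "SS"], res.between.loc[0, "SS"],
                   res.between.loc[1, "SS"]]
            assert np.allclose(got, oracle, rtol=1e-8)

    def test_matches_pingouin_on_balanced_design(self):
        pg = pytest.importorskip("pingouin")
        coh = make_cohort([10, 10, 10], seed=11, group_effects=(0, 1, 2),
                          session_effects=(0, .5, 1))
        res = cs.mixed_anova(coh, correction="none")
        ref = pg.mixed_anova(data=coh.rename(columns={"vhh": "dv"}), dv="dv",
                             within="session", subject="subject_id",
                             between="cgc", correction=False)
        ref = ref.set_index("Source")
        assert res.within.loc[0, "F"] == pytest.approx(ref.loc["session", "F"])
        assert res.within.loc[1, "F"] == pytest.approx(ref.loc["Interaction", "F"])
        assert res.between.loc[0, "F"] == pytest.approx(ref.loc["cgc", "F"])

    def test_df_bookkeeping(self, small_cohort):
        res = cs.mixed_anova(small_cohort, correction="none")
        n = small_cohort["subject_id"].nunique()
        g = small_cohort["cgc"].nunique()
        assert res.within.loc[0, "df"] == 2
        assert res.within.loc[2, "df"] == 2 * (n - g)
        assert res.between.loc[1, "df"] == n - g
        hf = cs.mixed_anova(small_cohort, correction="huynh-feldt")
        eps = hf.sphericity.eps_hf
        assert hf.within.loc[0, "df"] == pytest.approx(2 * eps)
        assert hf.within.loc[2, "df"] == pytest.approx(2 * (n - g) * eps)
        # F is unchanged by the correction; only dfs and p move
        assert hf.within.loc[0, "F"] == pytest.approx(res.within.loc[0, "F"])

    def test_unbalanced_sessions_rejected(self, small_cohort):
        broken = small_cohort.iloc[:-1]
        with pytest.raises(ValueError):
            cs.mixed_anova(broken)


class TestBonferroniPairwise:
    def test_antisymmetry(self, small_cohort):
        tab = cs.bonferroni_pairwise(small_cohort).set_index(["level_i", "level_j"])
        for i, j in ((1, 2), (1, 3), (2, 3)):
            assert tab.loc[(i, j), "mean_diff"] == -tab.loc[(j, i), "mean_diff"]
            assert tab.loc[(i, j), "se"] == tab.loc[(j, i), "se"]

    def test_noise_free_differences_equal_session_effects(self):
        spec = CohortSpec(n_subjects=30, subject_sd=0.0, residual_sd=0.0, seed=12)
        coh = generate_cohort(spec)
        tab = cs.bonferroni_pairwise(coh).set_index(["level_i", "level_j"])
        b2, b3 = spec.session_effects
        assert tab.loc[(1, 2), "mean_diff"] == pytest.approx(-b2, rel=1e-9)
        assert tab.loc[(1, 3), "mean_diff"] == pytest.approx(-b3, rel=1e-9)
        assert tab.loc[(2, 3), "mean_diff"] == pytest.approx(b2 - b3, rel=1e-6)

    def test_ci_contains_diff_and_p_in_range(self, small_cohort):
        tab = cs.bonferroni_pairwise(small_cohort)
        assert ((tab.ci_low <= tab.mean_diff) & (tab.mean_diff <= tab.ci_high)).all()
        assert tab.p_adjusted.between(0, 1).all()


class TestLevene:
    def test_null_rejection_rate(self):
        rng = np.random.default_rng(13)
        rejected = sum(
            cs.levene(rng.normal(0, 1, 90), np.repeat([0, 1, 2], 30))[1] < 0.05
            for _ in range(100))
        assert rejected <= 12  # ~5% nominal

    def test_power_against_sd_ratio_three(self):
        rng = np.random.default_rng(14)
        v = np.concatenate([rng.normal(0, 1, 100), rng.normal(0, 3, 100)])
        _, p = cs.levene(v, np.repeat([0, 1], 100))
        assert p < 0.01

    def test_identical_groups_give_zero(self):
        v = np.tile(np.arange(10.0), 2)
        f, _ = cs.levene(v, np.repeat([0, 1], 10))
        assert f == pytest.approx(0.0, abs=1e-12)


class TestWelchAnova:
    def test_equal_groups_give_zero_f(self):
        v = np.tile([1.0, 2.0, 4.0, 8.0], 3)
        f, *_ = cs.welch_anova(v, np.repeat([0, 1, 2], 4))
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equal_welch_t_squared(self):
        rng = np.random.default_rng(15)
        v = np.concatenate([rng.normal(0, 1, 25), rng.normal(1, 2, 35)])
        g = np.repeat([0, 1], [25, 35])
        f, df1, df2, p = cs.welch_anova(v, g)
        t, pt = sps.ttest_ind(v[g == 0], v[g == 1], equal_var=False)
        assert f == pytest.approx(t ** 2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-9)

    def test_matches_pingouin(self, small_cohort):
        pg = pytest.importorskip("pingouin")
        f, df1, df2, p = cs.welch_anova(small_cohort["vhh"], small_cohort["cgc"])
        ref = pg.welch_anova(dv="vhh", between="cgc", data=small_cohort)
        assert f == pytest.approx(ref.loc[0, "F"], rel=1e-9)
        assert df2 == pytest.approx(ref.loc[0, "ddof2"], rel=1e-9)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            cs.welch_anova([1.0, 1.0, 2.0, 3.0], [0, 0, 1, 1])


class TestGamesHowell:
    def test_equal_groups_give_p_one(self):
        v = np.tile([1.0, 2.0, 4.0, 8.0, 9.0], 3)
        tab = cs.games_howell(v, np.repeat([0, 1, 2], 5))
        assert (tab.p_adjusted > 0.999).all()

    def test_two_group_case_equals_welch_t(self):
        rng = np.random.default_rng(16)
        v = np.concatenate([rng.normal(0, 1, 20), rng.normal(1, 2, 30)])
        g = np.repeat([0, 1], [20, 30])
        tab = cs.games_howell(v, g)
        _, pt = sps.ttest_ind(v[g == 0], v[g == 1], equal_var=False)
        assert tab.iloc[0]["p_adjusted"] == pytest.approx(pt, abs=1e-6)

    def test_matches_pingouin(self, small_cohort):
        pg = pytest.importorskip("pingouin")
        ours = cs.games_howell(small_cohort["vhh"], small_cohort["cgc"])
        ours = ours[ours.level_i < ours.level_j].reset_index(drop=True)
        ref = pg.pairwise_gameshowell(dv="vhh", between="cgc", data=small_cohort)
        assert np.allclose(ours["mean_diff"], ref["diff"], rtol=1e-9)
        assert np.allclose(ours["se"], ref["se"] * np.sqrt(2), rtol=1e-9) or \
            np.allclose(ours["se"], ref["se"], rtol=1e-9)
        assert np.allclose(ours["p_adjusted"], ref["pval"], atol=1e-6)

    def test_ci_contains_diff(self, small_cohort):
        tab = cs.games_howell(small_cohort["vhh"], small_cohort["cgc"])
        assert ((tab.ci_low <= tab.mean_diff) & (tab.mean_diff <= tab.ci_high)).all()
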