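import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_hyp
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from prlcortex import stats as st
from prlcortex.datasets import load_md_cohort
from prlcortex.errors import (
    CollinearityError,
    DegenerateTestError,
    InvalidParameterError,
    UnbalancedDesignError,
)
from prlcortex.synthetic import CohortSpec, simulate_roi_table


# --------------------------------------------------------------------------
# Welch t
# --------------------------------------------------------------------------


class TestWelch:
    def test_cohort_prl_eccentricity(self):
        d = load_md_cohort()
        eo = d.loc[d["onset_group"] == "EO", "prl_ecc_deg"]
        lo = d.loc[d["onset_group"] == "LO", "prl_ecc_deg"]
        res = st.welch_t(eo, lo, labels=("EO", "LO"))
        assert round(res.mean_a, 1) == 12.2
        assert round(res.mean_b, 1) == 8.6
        assert round(res.sd_a, 1) == 4.1
        assert round(res.sd_b, 1) == 4.2
        assert round(res.t, 2) == 1.80
        assert round(res.df, 2) == 9.88
        assert round(res.p, 2) == 0.10

    def test_cohort_acuity(self):
        d = load_md_cohort()
        eo = d.loc[d["onset_group"] == "EO", "acuity_logmar"]
        lo = d.loc[d["onset_group"] == "LO", "acuity_logmar"]
        res = st.welch_t(lo, eo, labels=("LO", "EO"))
        assert round(res.mean_b, 2) == 1.12
        assert round(res.mean_a, 2) == 0.73
        assert round(res.t, 2) == -2.83
        assert round(res.df, 1) == 16.6
        assert round(res.p, 3) == 0.012

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 15)
        res = st.welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)
        assert res.df == pytest.approx(ref.df, rel=1e-12)

    def test_identical_samples_t_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        res = st.welch_t(a, a.copy())
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_direction_recorded(self):
        res = st.welch_t([1, 2, 3], [4, 5, 7], labels=("x", "y"))
        assert res.direction == "x - y"
        assert res.t < 0

    def test_errors(self):
        with pytest.raises(InvalidParameterError):
            st.welch_t([1.0], [1, 2, 3])
        with pytest.raises(DegenerateTestError):
            st.welch_t([1, 1, 1], [2, 2, 2])


# --------------------------------------------------------------------------
# BH adjustment
# --------------------------------------------------------------------------


class TestBH:
    def test_hand_computed_step_up(self):
        # p*(m/i): .04, .04, .04, .04 after the step-up minimum
        out = st.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert st.bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_all_ones(self):
        assert np.allclose(st.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @settings(max_examples=30, deadline=None)
    @given(
        st_hyp.lists(
            st_hyp.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=12
        )
    )
    def test_matches_statsmodels_and_monotone(self, pvals):
        mine = st.bh_adjust(pvals)
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(mine, ref)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(mine[order]) >= -1e-12).all()


# --------------------------------------------------------------------------
# sphericity
# --------------------------------------------------------------------------


class TestMauchlyHF:
    def test_compound_symmetry_is_spherical(self):
        cov = 0.3 * np.ones((4, 4)) + 0.7 * np.eye(4)
        w, p, gg, hf = st.mauchly_and_hf(cov, n=20, k=4)
        assert w == pytest.approx(1.0, abs=1e-12)
        assert gg == pytest.approx(1.0, abs=1e-12)
        assert hf == 1.0

    def test_toy_covariance_eigenvalue_oracle(self):
        cov = np.diag([1.0, 1.0, 100.0])
        w, p, gg, hf = st.mauchly_and_hf(cov, n=20, k=3)
        # independent oracle: epsilon from the eigenvalues of C' cov C
        C = st.orthonormal_contrasts(3)
        lam = np.linalg.eigvalsh(C.T @ cov @ C)
        gg_oracle = lam.sum() ** 2 / (2 * (lam**2).sum())
        assert gg == pytest.approx(gg_oracle, rel=1e-12)
        assert gg < 0.55  # near the 1/(k-1) = 0.5 lower bound
        w_oracle = np.prod(lam) / (lam.mean() ** 2)
        assert w == pytest.approx(w_oracle, rel=1e-12)

    def test_hf_at_least_gg(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            X = rng.normal(size=(30, 4))
            cov = np.cov(X.T)
            _, _, gg, hf = st.mauchly_and_hf(cov, n=30, k=4)
            assert hf >= gg - 1e-12

    def test_matches_pingouin_single_group(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 3)) @ np.diag([1.0, 1.5, 3.0])
        wide = pd.DataFrame(X, columns=["a", "b", "c"])
        cov = np.cov(X.T, ddof=1)
        w, p, gg, hf = st.mauchly_and_hf(cov, n=25, k=3, g=1)
        spher = pg.sphericity(wide)
        assert w == pytest.approx(spher.W, rel=1e-9)
        assert p == pytest.approx(spher.pval, rel=1e-9)
        assert gg == pytest.approx(pg.epsilon(wide, correction="gg"), rel=1e-9)
        assert hf == pytest.approx(pg.epsilon(wide, correction="hf"), rel=1e-9)

    def test_errors(self):
        with pytest.raises(InvalidParameterError):
            st.mauchly_and_hf(np.eye(2), n=10, k=2)


# --------------------------------------------------------------------------
# mixed ANOVA
# --------------------------------------------------------------------------


def _long_mixed(rng, n_per_group=12, k=3, group_effect=0.0, within_slope=0.5):
    rows = []
    for i in range(2 * n_per_group):
        grp = "A" if i < n_per_group else "B"
        b = rng.normal(0, 1)
        for j in range(k):
            rows.append(
                dict(
                    subject=f"s{i:02d}",
                    group=grp,
                    w=f"w{j}",
                    y=b
                    + within_slope * j
                    + (group_effect if grp == "A" else 0)
                    + rng.normal(0, 0.5 * (1 + j)),
                )
            )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_between_only_equals_pooled_t_squared(self):
        rng = np.random.default_rng(9)
        rows = [
            dict(subject=f"s{i}", group="A" if i < 10 else "B", w="only",
                 y=rng.normal(0.4 if i < 10 else 0.0, 1.0))
            for i in range(22)
        ]
        df = pd.DataFrame(rows)
        res = st.mixed_anova(df, "y", "w", "subject", ["group"])
        t = sps.ttest_ind(
            df.loc[df["group"] == "A", "y"], df.loc[df["group"] == "B", "y"],
            equal_var=True,
        )
        eff = res.effect("group")
        assert eff["F"] == pytest.approx(t.statistic**2, abs=1e-8)
        assert eff["p"] == pytest.approx(t.pvalue, abs=1e-10)

    def test_constant_dv_zero_ss(self):
        rows = [
            dict(subject=f"s{i}", group="A" if i < 4 else "B", w=w, y=1.0)
            for i in range(8)
            for w in ("w1", "w2")
        ]
        res = st.mixed_anova(pd.DataFrame(rows), "y", "w", "subject", ["group"])
        assert np.allclose(res.table["ss"], 0.0, atol=1e-20)
        assert res.table["F"].isna().all()

    def test_two_level_within_trivially_spherical(self):
        rng = np.random.default_rng(10)
        table, design = simulate_roi_table(CohortSpec(n_per_cell=6), seed=1)
        long = table.merge(design.reset_index(), on="participant")
        res = st.mixed_anova(
            long, "value", "roi_label", "participant", ["diagnosis", "onset"]
        )
        assert res.epsilon_hf == 1.0
        assert res.mauchly_w == 1.0
        assert (res.table["correction"] == "none").all()

    def test_matches_pingouin_one_between(self):
        df = _long_mixed(np.random.default_rng(3), group_effect=0.3)
        mine = st.mixed_anova(df, "y", "w", "subject", ["group"])
        ref = pg.mixed_anova(
            data=df, dv="y", within="w", subject="subject", between="group"
        ).set_index("Source")
        assert mine.effect("group")["F"] == pytest.approx(
            ref.loc["group", "F"], rel=1e-9
        )
        assert mine.effect("w")["F"] == pytest.approx(ref.loc["w", "F"], rel=1e-9)
        assert mine.effect("group:w")["F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )

    def test_matches_anovarm_no_between(self):
        df = _long_mixed(np.random.default_rng(4), k=4)
        mine = st.mixed_anova(df, "y", "w", "subject", [], sphericity_alpha=0.0)
        ref = AnovaRM(df, "y", "subject", within=["w"]).fit().anova_table
        assert mine.effect("w")["F"] == pytest.approx(
            ref.loc["w", "F Value"], rel=1e-9
        )
        assert mine.effect("w")["df1"] == ref.loc["w", "Num DF"]
        assert mine.effect("w")["df2"] == ref.loc["w", "Den DF"]

    def test_hf_correction_applied_when_nonspherical(self):
        rng = np.random.default_rng(11)
        rows = []
        for i in range(30):
            grp = "A" if i < 15 else "B"
            b = rng.normal(0, 0.2)
            for j in range(4):
                rows.append(
                    dict(subject=f"s{i}", group=grp, w=f"w{j}",
                         y=b + rng.normal(0, [0.1, 0.1, 0.1, 4.0][j]))
                )
        res = st.mixed_anova(pd.DataFrame(rows), "y", "w", "subject", ["group"])
        assert res.mauchly_p < 0.05
        w_row = res.effect("w")
        assert w_row["correction"] == "HF"
        assert w_row["df1"] == pytest.approx(3 * res.epsilon_hf)
        assert w_row["df2"] == pytest.approx(3 * 28 * res.epsilon_hf)
        # F itself is unchanged by the correction; p recomputed from new dfs
        assert w_row["p"] == pytest.approx(
            sps.f.sf(w_row["F"], w_row["df1"], w_row["df2"])
        )

    def test_missing_within_level_names_participant(self):
        table, design = simulate_roi_table(CohortSpec(n_per_cell=3), seed=2)
        long = table.merge(design.reset_index(), on="participant")
        broken = long[
            ~((long["participant"] == "S002") & (long["roi_label"] == "roi2"))
        ]
        with pytest.raises(UnbalancedDesignError, match="S002"):
            st.mixed_anova(
                broken, "value", "roi_label", "participant", ["diagnosis", "onset"]
            )

    def test_small_cell_rejected(self):
        table, design = simulate_roi_table(CohortSpec(n_per_cell=3), seed=3)
        design = design.copy()
        design.loc[design.index[:11], "diagnosis"] = "MD"
        long = table.merge(design.reset_index(), on="participant")
        with pytest.raises(InvalidParameterError):
            st.mixed_anova(
                long, "value", "roi_label", "participant", ["diagnosis"]
            )

    def test_permutation_oracle_between_effect(self):
        # parametric p for the diagnosis effect vs a label-permutation null
        spec = CohortSpec(
            n_per_cell=4, effect_diagnosis=0.4, noise_sd=0.3, participant_sd=0.4
        )
        table, design = simulate_roi_table(spec, seed=14)
        long = table.merge(design.reset_index(), on="participant")
        res = st.mixed_anova(
            long, "value", "roi_label", "participant", ["diagnosis", "onset"]
        )
        p_param = res.effect("diagnosis")["p"]

        # independent permutation machinery on subject means
        wide = long.pivot_table(index="participant", columns="roi_label",
                                values="value")
        yb = wide.mean(axis=1).to_numpy()
        design = design.loc[wide.index]
        onset = np.where(design["onset"] == "early", 1.0, -1.0)
        diag_obs = np.where(design["diagnosis"] == "MD", 1.0, -1.0)

        def f_stat(diag):
            X = np.column_stack([np.ones_like(yb), diag, onset, diag * onset])
            rss_f = np.sum((yb - X @ np.linalg.lstsq(X, yb, rcond=None)[0]) ** 2)
            Xr = X[:, [0, 2]]  # drop diagnosis and its interaction column? no:
            Xr = np.column_stack([np.ones_like(yb), onset, diag * onset])
            rss_r = np.sum((yb - Xr @ np.linalg.lstsq(Xr, yb, rcond=None)[0]) ** 2)
            return (rss_r - rss_f) / (rss_f / (len(yb) - 4))

        f_obs = f_stat(diag_obs)
        rng = np.random.default_rng(15)
        hits = 0
        B = 2000
        for _ in range(B):
            hits += f_stat(rng.permutation(diag_obs)) >= f_obs
        p_perm = (hits + 1) / (B + 1)
        assert abs(p_param - p_perm) < 0.05


# --------------------------------------------------------------------------
# ANCOVA
# --------------------------------------------------------------------------


class TestAncova:
    def _with_cov(self, seed, beta=0.0, n_per_cell=10):
        rng = np.random.default_rng(seed)
        table, design = simulate_roi_table(
            CohortSpec(n_per_cell=n_per_cell, participant_sd=0.3, noise_sd=0.1),
            seed=seed,
        )
        design = design.copy()
        cov = rng.normal(0, 1, size=len(design))
        design["cov"] = cov
        long = table.merge(design.reset_index(), on="participant")
        long["value"] = long["value"] + beta * long["cov"]
        return long

    def test_uncorrelated_covariate_leaves_effects(self):
        long = self._with_cov(seed=20, beta=0.0, n_per_cell=40)
        a = st.mixed_anova(
            long, "value", "roi_label", "participant", ["diagnosis", "onset"]
        )
        b = st.mixed_ancova(
            long, "value", "roi_label", "participant", ["diagnosis", "onset"],
            covariates=["cov"],
        )
        for eff in ("diagnosis", "onset", "diagnosis:onset"):
            assert abs(a.effect(eff)["p"] - b.effect(eff)["p"]) < 0.06

    def test_covariate_detected_and_groups_calibrated(self):
        long = self._with_cov(seed=21, beta=1.0)
        res = st.mixed_ancova(
            long, "value", "roi_label", "participant", ["diagnosis", "onset"],
            covariates=["cov"],
        )
        assert res.effect("cov")["p"] < 1e-6
        # null calibration of the group effects over replicates
        reps, alpha = 300, 0.05
        rej = {e: 0 for e in ("diagnosis", "onset", "diagnosis:onset")}
        for r in range(reps):
            lr = self._with_cov(seed=1000 + r, beta=1.0, n_per_cell=5)
            rr = st.mixed_ancova(
                lr, "value", "roi_label", "participant", ["diagnosis", "onset"],
                covariates=["cov"],
            )
            for e in rej:
                rej[e] += rr.effect(e)["p"] < alpha
        for e, n_rej in rej.items():
            assert abs(n_rej / reps - alpha) < 0.035, e

    def test_zero_variance_covariate_raises(self):
        long = self._with_cov(seed=22)
        long["cov"] = 0.0
        with pytest.raises(CollinearityError):
            st.mixed_ancova(
                long, "value", "roi_label", "participant", ["diagnosis", "onset"],
                covariates=["cov"],
            )

    def test_requires_covariates(self):
        long = self._with_cov(seed=23)
        with pytest.raises(InvalidParameterError):
            st.mixed_ancova(
                long, "value", "roi_label", "participant", ["diagnosis"],
                covariates=[],
            )

    def test_covariate_must_be_between_level(self):
        long = self._with_cov(seed=24)
        long["cov"] = np.arange(len(long), dtype=float)  # varies within subject
        with pytest.raises(InvalidParameterError):
            st.mixed_ancova(
                long, "value", "roi_label", "participant", ["diagnosis"],
                covariates=["cov"],
            )


# --------------------------------------------------------------------------
# covariate preparation
# --------------------------------------------------------------------------


class TestPrepareCovariates:
    def _table(self):
        rows = []
        for pid, ecc, size in (("MD001", 8.0, 100), ("HC001", 2.0, 80),
                               ("MD002", 12.0, 60), ("HC002", 3.0, 120)):
            for roi in ("cPRL", "cURL"):
                rows.append(dict(participant=pid, roi_label=roi, metric="ficvf",
                                 value=0.4, n_vertices=size, mean_ecc=ecc))
        table = pd.DataFrame(rows)
        design = pd.DataFrame(
            {
                "participant": ["MD001", "HC001", "MD002", "HC002"],
                "diagnosis": ["MD", "HC", "MD", "HC"],
                "onset": ["early", "early", "late", "late"],
                "matched_id": ["HC001", "MD001", "HC002", "MD002"],
            }
        ).set_index("participant")
        return table, design

    def test_ecc_shared_and_log_centered(self):
        table, design = self._table()
        out = st.prepare_covariates(table, design)
        # controls inherit the matched patient's eccentricity -> pairwise equal
        assert out.loc["HC001", "cov_ecc"] == out.loc["MD001", "cov_ecc"]
        assert out.loc["HC002", "cov_ecc"] == out.loc["MD002", "cov_ecc"]
        assert out["cov_ecc"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["cov_size"].mean() == pytest.approx(0.0, abs=1e-12)
        # log transform: shared values are log(8) and log(12), centred
        expected = np.log([8.0, 8.0, 12.0, 12.0])
        expected -= expected.mean()
        assert np.allclose(out["cov_ecc"].to_numpy(), expected)

    def test_size_not_logged(self):
        table, design = self._table()
        out = st.prepare_covariates(table, design)
        sizes = np.array([100.0, 80.0, 60.0, 120.0])
        assert np.allclose(out["cov_size"].to_numpy(), sizes - sizes.mean())


# --------------------------------------------------------------------------
# post-hoc FDR
# --------------------------------------------------------------------------


class TestPosthoc:
    def _data(self, seed=0, effect_by_roi=(0.8, 0.0, 0.0, 0.0)):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(24):
            grp = "MD" if i < 12 else "HC"
            for k, eff in enumerate(effect_by_roi):
                rows.append(
                    dict(participant=f"s{i}", diagnosis=grp, roi_label=f"roi{k}",
                         value=rng.normal(eff if grp == "MD" else 0.0, 0.5))
                )
        return pd.DataFrame(rows)

    def test_single_roi_adjusted_equals_raw(self):
        df = self._data(effect_by_roi=(0.5,))
        out = st.posthoc_fdr(df, "value", "diagnosis", "roi_label")
        assert out["p_fdr"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_detects_effect_roi(self):
        df = self._data(seed=1)
        out = st.posthoc_fdr(df, "value", "diagnosis", "roi_label").set_index("roi")
        assert out.loc["roi0", "significant"]
        assert out.loc["roi0", "t"] > 0  # MD - HC ordering

    def test_all_p_one_none_significant(self):
        df = self._data(seed=2, effect_by_roi=(0.0, 0.0, 0.0, 0.0))
        out = st.posthoc_fdr(df, "value", "diagnosis", "roi_label", q=1e-6)
        assert not out["significant"].any()

    def test_welch_per_roi(self):
        df = self._data(seed=3)
        out = st.posthoc_fdr(df, "value", "diagnosis", "roi_label").set_index("roi")
        sub = df[df["roi_label"] == "roi1"]
        ref = st.welch_t(
            sub.loc[sub["diagnosis"] == "MD", "value"],
            sub.loc[sub["diagnosis"] == "HC", "value"],
        )
        assert out.loc["roi1", "t"] == pytest.approx(ref.t)
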