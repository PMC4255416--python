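"""Composites, effect sizes, ANCOVA, backwards elimination, stepwise VOIs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import lesionvol.statistics as st
from lesionvol.errors import CollinearityError, InputError, UndefinedEffectError
from lesionvol.synthetic_data import (generate_cohort, standardized_effects_spec,
                                      voi_cohort_spec)


def lstsq_elimination_oracle(df, outcome, candidates, alpha=0.05):
    """Independent reimplementation: explicit repeated full refits with
    numpy lstsq and scipy t-tests, same tie rule (smaller |beta| first)."""
    work = (df - df.mean()) / df.std(ddof=1)
    y = work[outcome].to_numpy()
    current = list(candidates)
    while current:
        X = np.column_stack([np.ones(len(work))] + [work[c].to_numpy() for c in current])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = len(y) - X.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        pvals = 2 * sps.t.sf(np.abs(tvals), dof)
        over = [(c, pvals[i + 1], abs(beta[i + 1]))
                for i, c in enumerate(current) if pvals[i + 1] > alpha]
        if not over:
            break
        worst = max(p for _, p, _ in over)
        drop = min((c for c, p, b in over if p == worst),
                   key=lambda c: next(b for cc, p, b in over if cc == c))
        current.remove(drop)
    return current


class TestCompositeScores:
    def _battery(self):
        nc = pd.DataFrame({
            "fas_fluency": [40.0, 50.0, 60.0],
            "wcst_categories": [4.0, 5.0, 6.0],
            "wcst_perseverative_errors": [10.0, 20.0, 30.0],
            "trails_a_time": [30.0, 40.0, 50.0],
            "cvlt_total": [40.0, 50.0, 60.0],
            "wms_visual_reproduction": [30.0, 35.0, 40.0],
            "drs_memory": [20.0, 22.0, 24.0],
        }, index=["nc1", "nc2", "nc3"])
        return nc

    def test_subject_at_reference_mean_scores_zero_everywhere(self):
        nc = self._battery()
        probe = nc.mean().to_frame().T
        probe.index = ["probe"]
        table = pd.concat([nc, probe])
        comp = st.composite_score(table, nc.index)
        assert np.allclose(comp.loc["probe"], 0.0)

    def test_one_sd_better_on_every_executive_test_scores_one(self):
        nc = self._battery()
        probe = nc.mean()
        for t in st.DEFAULT_DOMAIN_MAP["executive"]:
            probe[t] += st.DEFAULT_ORIENTATION[t] * nc[t].std(ddof=1)
        table = pd.concat([nc, probe.to_frame().T.set_axis(["probe"])])
        comp = st.composite_score(table, nc.index)
        assert comp.loc["probe", "executive"] == pytest.approx(1.0)

    def test_slower_trails_a_flips_to_negative_speed_composite(self):
        nc = self._battery()
        probe = nc.mean()
        probe["trails_a_time"] += nc["trails_a_time"].std(ddof=1)  # 1 SD slower
        table = pd.concat([nc, probe.to_frame().T.set_axis(["probe"])])
        comp = st.composite_score(table, nc.index)
        assert comp.loc["probe", "speed"] == pytest.approx(-1.0)

    def test_subject_missing_all_domain_tests_gets_missing_composite(self):
        nc = self._battery()
        probe = nc.mean()
        probe["trails_a_time"] = np.nan
        table = pd.concat([nc, probe.to_frame().T.set_axis(["probe"])])
        comp = st.composite_score(table, nc.index)
        assert np.isnan(comp.loc["probe", "speed"])
        assert comp.loc["probe", "memory"] == pytest.approx(0.0)


class TestCohensD:
    @pytest.mark.parametrize("m1,s1,m2,s2,expect", [
        (72.8, 9.0, 69.5, 8.0, 0.38),    # age
        (13.8, 3.8, 15.5, 3.0, 0.47),    # education, years
        (23.2, 4.5, 29.0, 1.1, 1.49),    # MMSE
        (73.1, 4.6, 79.0, 3.7, 1.35),    # BPF %
    ])
    def test_reproduces_printed_group_effect_sizes(self, m1, s1, m2, s2, expect):
        es = st.cohens_d_pooled(m1, s1, 265, m2, s2, 100)
        assert round(es.magnitude, 2) == expect

    def test_equal_means_give_zero(self):
        assert st.cohens_d_pooled(5.0, 1.0, 10, 5.0, 2.0, 10).d == 0.0

    def test_zero_pooled_sd_is_undefined(self):
        with pytest.raises(UndefinedEffectError):
            st.cohens_d_pooled(1.0, 0.0, 10, 2.0, 0.0, 10)


class TestAncova:
    def _cohort(self, n, offset, seed):
        rng = np.random.default_rng(seed)
        half = n // 2
        df = pd.DataFrame({
            "group": ["AD"] * half + ["NC"] * half,
            "age": rng.normal(70, 8, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.normal(14, 3, n),
        })
        df["y"] = rng.standard_normal(n)
        df.loc[df["group"] == "NC", "y"] += offset
        return df

    def test_recovers_group_offset(self):
        df = self._cohort(400, 0.5, 1)
        est, t, p, fit = st.ancova_group_difference(df, "y")
        se = fit.bse[1]
        assert abs(est - 0.5) < 2 * se
        assert p < 0.01

    def test_null_p_values_are_roughly_uniform(self):
        ps = []
        for seed in range(200):
            df = self._cohort(200, 0.0, seed)
            ps.append(st.ancova_group_difference(df, "y")[2])
        rate = np.mean(np.array(ps) < 0.05)
        assert 0.01 <= rate <= 0.10

    def test_constant_covariate_is_a_collinearity_error(self):
        df = self._cohort(100, 0.0, 3)
        df["education"] = 12.0
        with pytest.raises(CollinearityError, match="education"):
            st.ancova_group_difference(df, "y")


class TestBackwardsElimination:
    def test_strong_signal_retained(self):
        spec = standardized_effects_spec("y", {"x": 0.5}, n=200, seed=0)
        df = generate_cohort(spec)
        res = st.backwards_elimination(df, "y", ["x"])
        assert res.retained_names() == ["x"]
        assert res.retained["p"].iloc[0] < 0.05

    def test_pure_noise_predictor_is_eliminated_in_most_reps(self):
        removed = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"y": rng.standard_normal(500),
                               "x": rng.standard_normal(500)})
            res = st.backwards_elimination(df, "y", ["x"])
            removed += "x" not in res.retained_names()
        assert removed / reps >= 0.90

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_explicit_refit_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 60, 4
        X = rng.standard_normal((n, k))
        beta = np.array([0.6, 0.25, 0.0, 0.0])
        y = X @ beta + rng.standard_normal(n)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(k)])
        df["y"] = y
        res = st.backwards_elimination(df, "y", [f"x{i}" for i in range(k)])
        want = lstsq_elimination_oracle(df, "y", [f"x{i}" for i in range(k)])
        assert res.retained_names() == want

    def test_forced_covariates_are_never_removed(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"y": rng.standard_normal(100),
                           "x": rng.standard_normal(100),
                           "age": rng.standard_normal(100)})
        res = st.backwards_elimination(df, "y", ["x"], forced=["age"])
        assert "age" in res.retained_names()

    def test_candidate_limit_enforced(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((30, 8)),
                          columns=[f"x{i}" for i in range(7)] + ["y"])
        with pytest.raises(InputError, match="limit"):
            st.backwards_elimination(df, "y", [f"x{i}" for i in range(7)])

    def test_all_noise_yields_intercept_only_with_elimination_trace(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"y": rng.standard_normal(300),
                           "a": rng.standard_normal(300),
                           "b": rng.standard_normal(300)})
        res = st.backwards_elimination(df, "y", ["a", "b"], alpha=1e-6)
        assert res.retained_names() == []
        assert [e[0] for e in res.eliminated] and len(res.eliminated) == 2


class TestStepwise:
    LOBES = {lobe: [f"{lobe}_{i}" for i in range(5)]
             for lobe in ("frontal", "parietal", "temporal", "occipital")}

    def test_planted_subregion_is_localized(self):
        spec = voi_cohort_spec(self.LOBES, {"temporal_2": 0.4}, n=400, seed=3)
        df = generate_cohort(spec)
        res = st.stepwise_voi_analysis(df, "cognition", self.LOBES)
        assert "temporal" in res.localized_lobes
        assert "temporal_2" in res.stage2["temporal"].retained_names()

    def test_covariate_only_signal_retains_no_voi(self):
        spec = voi_cohort_spec(self.LOBES, {}, covariate_betas={"bpf": 0.5},
                               n=400, seed=4)
        df = generate_cohort(spec)
        res = st.stepwise_voi_analysis(df, "cognition", self.LOBES,
                                       covariates=["bpf"])
        assert res.localized_lobes == []
        assert res.final() is res.stage1


class TestPartialRegression:
    def test_no_covariates_returns_centered_series(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": rng.standard_normal(50),
                           "x": rng.standard_normal(50)})
        xr, yr, slope = st.partial_regression_data(df, "y", "x")
        assert np.allclose(xr, df["x"] - df["x"].mean())
        assert np.allclose(yr, df["y"] - df["y"].mean())

    @pytest.mark.parametrize("seed", range(5))
    def test_frisch_waugh_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        df = pd.DataFrame({
            "x": rng.standard_normal(n), "a": rng.standard_normal(n),
            "b": rng.standard_normal(n)})
        df["y"] = 0.3 * df["x"] - 0.2 * df["a"] + rng.standard_normal(n)
        _, _, slope = st.partial_regression_data(df, "y", "x", ["a", "b"])
        import statsmodels.api as sm
        X = sm.add_constant(df[["x", "a", "b"]].to_numpy())
        joint = sm.OLS(df["y"].to_numpy(), X).fit().params[1]
        assert slope == pytest.approx(joint, abs=1e-10)

    def test_recovers_planted_atrophy_lesion_coefficient(self):
        # pvSH -> BPF standardized coefficient of -0.14 with covariates
        spec = standardized_effects_spec(
            "bpf", {"pvsh": -0.14, "education": -0.16, "mmse": 0.12},
            n=2000, seed=8)
        df = generate_cohort(spec)
        zdf = (df[["bpf", "pvsh", "education", "mmse"]]
               - df[["bpf", "pvsh", "education", "mmse"]].mean()) / \
            df[["bpf", "pvsh", "education", "mmse"]].std(ddof=1)
        _, _, slope = st.partial_regression_data(zdf, "bpf", "pvsh",
                                                 ["education", "mmse"])
        se = 1.0 / np.sqrt(len(df))
        assert abs(slope - (-0.14)) < 2 * se
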