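import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from oracles import bh_stepup, nb_mle_two_group_grid
from riboclean import bh_adjust, fit_nb_glm, lrt_full_vs_reduced, wald_contrast
from riboclean.errors import ContractError, DesignError
from riboclean.glm import LOG2E, NBGLMFit


def _two_group_design(n_per_group: int) -> pd.DataFrame:
    idx = [f"s{j}" for j in range(2 * n_per_group)]
    return pd.DataFrame(
        {"intercept": 1.0, "grp": [0.0] * n_per_group + [1.0] * n_per_group},
        index=idx,
    )


def _nb_counts(rng, mu, alpha, n_samples):
    r = 1 / alpha
    return rng.negative_binomial(r[:, None], (r / (r + mu))[:, None],
                                 size=(len(mu), n_samples))


def _frame(arr):
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=[f"s{j}" for j in range(arr.shape[1])])


class TestBH:
    def test_hand_computed_step_up(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.9]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.9])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_textbook_procedure_on_random_vectors(self, pvals):
        np.testing.assert_allclose(bh_adjust(np.array(pvals)), bh_stepup(pvals),
                                   atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30))
    def test_monotone_in_p(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestWaldContrast:
    def _fit_with(self, log2fc, se_log2):
        """Minimal single-coefficient fit with a prescribed estimate/se."""
        est = log2fc / LOG2E
        var = (se_log2 / LOG2E) ** 2
        design = pd.DataFrame({"c": [1.0]}, index=["s0"])
        return NBGLMFit(
            genes=pd.Index(["g0"]), design=design,
            coef=np.array([[est]]), cov=np.array([[[var]]]),
            dispersion=np.array([0.1]), mu=np.array([[1.0]]),
            converged=np.array([True]), loglik=np.array([0.0]),
            size_factors=pd.Series([1.0], index=["s0"]),
            mean_norm_count=np.array([1.0]),
        )

    def test_zero_estimate_gives_p_one(self):
        res = wald_contrast(self._fit_with(0.0, 0.5), "c")
        assert res.table["p"].iloc[0] == 1.0

    def test_known_estimate_se_pair(self):
        res = wald_contrast(self._fit_with(1.0, 0.5), "c")
        row = res.table.iloc[0]
        assert row["stat"] == pytest.approx(2.0, rel=1e-9)
        assert row["p"] == pytest.approx(2 * stats.norm.sf(2.0), rel=1e-9)
        assert row["p"] == pytest.approx(0.0455, abs=2e-4)

    def test_unknown_coefficient_is_contract_error(self):
        with pytest.raises(ContractError, match="unknown coefficient"):
            wald_contrast(self._fit_with(1.0, 0.5), "nope")

    def test_extreme_lfc_capped_and_flagged(self):
        res = wald_contrast(self._fit_with(25.0, 0.5), "c")
        assert res.table["log2fc"].iloc[0] == 10.0
        assert "lfc_capped" in res.table["flag"].iloc[0]


class TestFitNBGLM:
    def test_large_count_small_dispersion_recovers_mean_ratio(self):
        """In the near-Poisson, large-count limit the fitted log2fc equals
        the log2 ratio of normalized group means."""
        rng = np.random.default_rng(3)
        mu = np.array([5e4, 2e4])
        counts = np.column_stack([
            rng.poisson(mu, size=(3, 2)).T, rng.poisson(4 * mu, size=(3, 2)).T
        ])
        df = _frame(counts)
        sf = pd.Series(np.ones(6), index=df.columns)
        fit = fit_nb_glm(df, _two_group_design(3), size_factors=sf,
                         dispersion=np.full(2, 1e-8))
        ratio = counts[:, 3:].mean(axis=1) / counts[:, :3].mean(axis=1)
        np.testing.assert_allclose(fit.coef[:, 1] * LOG2E, np.log2(ratio), atol=1e-3)

    def test_coefficients_match_grid_search_oracle(self):
        """MLE coefficients agree with a brute-force likelihood grid on a
        5-gene toy with fixed dispersion and unequal size factors."""
        rng = np.random.default_rng(11)
        mu = np.array([20.0, 80.0, 300.0, 55.0, 900.0])
        counts = _nb_counts(rng, mu, np.full(5, 0.1), 6)
        counts[2, 3:] = (counts[2, 3:] * 3).astype(int)
        df = _frame(counts)
        sf = pd.Series([0.8, 1.0, 1.2, 0.9, 1.1, 1.0], index=df.columns)
        alpha = np.full(5, 0.1)
        fit = fit_nb_glm(df, _two_group_design(3), size_factors=sf, dispersion=alpha)
        groups = np.array([0, 0, 0, 1, 1, 1])
        for g in range(5):
            b0, b1 = nb_mle_two_group_grid(
                counts[g].astype(float), sf.to_numpy(), groups, 0.1
            )
            assert fit.coef[g, 0] == pytest.approx(b0, abs=1e-3)
            assert fit.coef[g, 0] + fit.coef[g, 1] == pytest.approx(b1, abs=1e-3)

    def test_identical_groups_give_small_lfc_and_uniformish_p(self):
        rng = np.random.default_rng(5)
        mu = rng.lognormal(np.log(500), 0.5, 300)
        counts = _nb_counts(rng, mu, np.full(300, 0.02), 12)
        df = _frame(counts)
        fit = fit_nb_glm(df, _two_group_design(6),
                         size_factors=pd.Series(np.ones(12), index=df.columns))
        res = wald_contrast(fit, "grp")
        assert np.median(np.abs(res.table["log2fc"])) < 0.1
        # p-values roughly uniform: each quartile holds 15-35% of genes
        hist, _ = np.histogram(res.table["p"], bins=4, range=(0, 1))
        assert (hist / 300 > 0.10).all() and (hist / 300 < 0.40).all()

    def test_rank_deficient_design_names_aliased_columns(self, tiny_cm):
        design = pd.DataFrame(
            {"intercept": 1.0, "a": [1.0, 0, 1, 0], "b": [1.0, 0, 1, 0]},
            index=tiny_cm.sample_ids,
        )
        with pytest.raises(DesignError, match="b"):
            fit_nb_glm(tiny_cm, design)


class TestLRT:
    def _fits(self, effect: float, rng, n=6, G=200, alpha=0.05):
        mu = rng.lognormal(np.log(400), 0.5, G)
        base = _nb_counts(rng, mu, np.full(G, alpha), n)
        scaled = _nb_counts(rng, mu * 2.0**effect, np.full(G, alpha), n)
        counts = np.column_stack([base, scaled])
        df = _frame(counts)
        sf = pd.Series(np.ones(2 * n), index=df.columns)
        full = _two_group_design(n)
        reduced = full[["intercept"]]
        fit_f = fit_nb_glm(df, full, size_factors=sf)
        fit_r = fit_nb_glm(df, reduced, size_factors=sf,
                           dispersion=fit_f.dispersion)
        return fit_f, fit_r

    def test_identical_designs_give_zero_stat_and_p_one(self):
        rng = np.random.default_rng(2)
        fit_f, _ = self._fits(0.0, rng)
        res = lrt_full_vs_reduced(fit_f, fit_f)
        assert np.allclose(res.table["stat"], 0.0, atol=1e-8)
        assert (res.table["p"] == 1.0).all()

    def test_df_equals_rank_difference(self):
        rng = np.random.default_rng(2)
        fit_f, fit_r = self._fits(0.0, rng, G=20)
        res = lrt_full_vs_reduced(fit_f, fit_r)
        assert (res.table["df"] == 1).all()

    def test_power_above_90pct_at_two_log2_units(self):
        """Genes simulated with a 2-log2-unit group effect are detected at
        p<0.05 in >90% of 200 replicate genes."""
        rng = np.random.default_rng(8)
        fit_f, fit_r = self._fits(2.0, rng)
        res = lrt_full_vs_reduced(fit_f, fit_r)
        assert (res.table["p"] < 0.05).mean() > 0.9

    def test_non_nested_designs_rejected(self):
        rng = np.random.default_rng(2)
        fit_f, fit_r = self._fits(0.0, rng, G=20)
        other = fit_r.design.copy()
        other["weird"] = np.resize([1.0, -1.0, 0.5], len(other))
        fit_other = fit_nb_glm(
            _frame(np.full((20, 12), 50)), other,
            size_factors=pd.Series(np.ones(12), index=other.index),
            dispersion=np.full(20, 0.05),
        )
        with pytest.raises(ContractError, match="nested"):
            lrt_full_vs_reduced(fit_f, fit_other)

    def test_wald_and_lrt_agree_in_gentle_regime(self):
        """Large counts, small effects: the two tests' p-values agree within
        ~20% for the bulk of genes."""
        rng = np.random.default_rng(13)
        fit_f, fit_r = self._fits(0.4, rng, n=8, G=200, alpha=0.01)
        lrt = lrt_full_vs_reduced(fit_f, fit_r)
        wald = wald_contrast(fit_f, "grp")
        p_w, p_l = wald.table["p"].to_numpy(), lrt.table["p"].to_numpy()
        mask = (p_l > 1e-6) & (p_w > 1e-6)
        rel = np.abs(np.log(p_w[mask]) - np.log(p_l[mask]))
        assert np.median(rel) < 0.2
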