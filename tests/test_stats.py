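import numpy as np
import pandas as pd
import pytest
from actirhythm.simulate import CognitiveLink, simulate_cohort_table
from actirhythm.stats import (
    HierarchicalRhythmModel,
    PermutationAnova,
    anova_with_gate,
    holm_correct,
    kruskal_wallis_per_factor,
    residual_normality_gate,
)
class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_correct([0.04])[0] == pytest.approx(0.04)
    def test_hand_computed_example(self):
        np.testing.assert_allclose(holm_correct([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04])
    def test_dominates_raw_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 12)
        c = holm_correct(p)
        assert (c >= p).all() and (c <= 1).all()
    def test_order_invariant_and_deterministic(self):
        p = np.array([0.2, 0.001, 0.04, 0.04, 0.7])
        c = holm_correct(p)
        perm = np.array([3, 0, 4, 1, 2])
        np.testing.assert_allclose(holm_correct(p[perm]), c[perm])
        np.testing.assert_allclose(holm_correct(p), c, atol=0)
    def test_matches_stepdown_oracle(self):
        # independent step-down implementation
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 0.3, 8)
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        np.testing.assert_allclose(holm_correct(p), adj, rtol=1e-12)
def _kw_oracle(groups):
    """Tie-corrected Kruskal-Wallis H computed from first principles."""
    flat = np.concatenate(groups)
    n = len(flat)
    order = flat.argsort(kind="mergesort")
    ranks = np.empty(n)
    i = 0
    s = flat[order]
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    pos = 0
    h = 0.0
    for g in groups:
        r = ranks[pos:pos + len(g)]
        h += r.sum() ** 2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(flat, return_counts=True)
    tie = 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / tie
class TestKruskalWallis:
    def test_identical_values(self):
        df = pd.DataFrame({"y": [5.0] * 9, "g": list("abc") * 3})
        h, p = kruskal_wallis_per_factor(df, "y", "g")
        assert h == 0.0 and p == 1.0
    def test_matches_rank_oracle_small_n(self):
        groups = [np.array([1.0, 4.0, 6.0]), np.array([2.0, 3.0]), np.array([5.0, 8.0, 7.0])]
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": ["a"] * 3 + ["b"] * 2 + ["c"] * 3,
        })
        h, _ = kruskal_wallis_per_factor(df, "y", "g")
        assert h == pytest.approx(_kw_oracle(groups), rel=1e-12)
    def test_tie_correction_matches_oracle(self):
        groups = [np.array([1.0, 1.0, 2.0, 3.0]), np.array([2.0, 2.0, 3.0, 3.0])]
        df = pd.DataFrame({"y": np.concatenate(groups), "g": ["a"] * 4 + ["b"] * 4})
        h, _ = kruskal_wallis_per_factor(df, "y", "g")
        assert h == pytest.approx(_kw_oracle(groups), rel=1e-12)
def _factorial_frame(y, rng=None):
    n = len(y)
    groups = ["DS", "TD"] * (n // 2)
    ages = [a for a in ("child", "adolescent", "adult") for _ in range(n // 3)]
    ages = (ages * 2)[:n]
    return pd.DataFrame({"y": y, "group": groups[:n], "age_group": ages})
class TestNormalityGate:
    def test_gaussian_prefers_permutation(self):
        picks = []
        for s in range(20):
            y = np.random.default_rng(s).normal(0, 1, 60)
            picks.append(residual_normality_gate(_factorial_frame(y), "y",
                                                 ["group", "age_group"]))
        assert np.mean([p == "permutation" for p in picks]) >= 0.9
    def test_heavy_tails_prefer_ranks(self):
        picks = []
        for s in range(20):
            y = np.random.default_rng(s).standard_t(1, 60)
            picks.append(residual_normality_gate(_factorial_frame(y), "y",
                                                 ["group", "age_group"]))
        assert np.mean([p == "kruskal_wallis" for p in picks]) >= 0.9
    def test_constant_outcome_errors(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            residual_normality_gate(_factorial_frame(np.ones(30)), "y",
                                    ["group", "age_group"])
class TestPermutationAnova:
    def test_constant_outcome_gives_p_one(self):
        df = _factorial_frame(np.full(36, 7.0))
        res = PermutationAnova(df, "y", ["group", "age_group"]).fit(n_perm=199, seed=0)
        for term in res.terms:
            assert res.statistics[term] == 0.0
            assert res.pvalues[term] == 1.0
    def test_strong_single_factor_effect(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(5, 1, 20)])
        df = pd.DataFrame({"y": y, "group": ["DS"] * 20 + ["TD"] * 20})
        res = PermutationAnova(df, "y", ["group"]).fit(n_perm=9999, seed=0)
        assert res.pvalues["group"] <= 0.001
    def test_reproducible_and_stable_across_seeds(self):
        rng = np.random.default_rng(2)
        df = _factorial_frame(rng.normal(0, 1, 60) + np.repeat([0, 0.8], 30))
        a = PermutationAnova(df, "y", ["group", "age_group"]).fit(n_perm=9999, seed=42)
        b = PermutationAnova(df, "y", ["group", "age_group"]).fit(n_perm=9999, seed=42)
        assert a.pvalues == b.pvalues  # bit-exact under a fixed seed
        c = PermutationAnova(df, "y", ["group", "age_group"]).fit(n_perm=9999, seed=7)
        for t in a.terms:
            assert abs(a.pvalues[t] - c.pvalues[t]) <= 0.011
    def test_f_matches_statsmodels_type2_on_balanced_design(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(3)
        df = _factorial_frame(rng.normal(0, 1, 60) + np.repeat([0, 1.0], 30))
        res = PermutationAnova(df, "y", ["group", "age_group"]).fit(n_perm=99, seed=0)
        ols = smf.ols("y ~ C(group) * C(age_group)", data=df).fit()
        tbl = sm.stats.anova_lm(ols, typ=2)
        assert res.statistics["group"] == pytest.approx(tbl.loc["C(group)", "F"], rel=1e-8)
        assert res.statistics["age_group"] == pytest.approx(
            tbl.loc["C(age_group)", "F"], rel=1e-8)
        assert res.statistics["group:age_group"] == pytest.approx(
            tbl.loc["C(group):C(age_group)", "F"], rel=1e-8)
    def test_gate_dispatches_to_kruskal(self):
        y = np.random.default_rng(11).standard_t(1, 60)
        res = anova_with_gate(_factorial_frame(y), "y", ["group", "age_group"],
                              n_perm=99, seed=0)
        assert res.method == "kruskal_wallis"
        assert set(res.terms) == {"group", "age_group"}
class TestHierarchicalModel:
    def _table(self, seed=0, n=60, beta_is=0.0):
        betas = {"y": CognitiveLink(2.0, beta_is, 0.1, 1.0)}
        return simulate_cohort_table(n, betas, seed=seed)
    def test_planted_outlier_excluded_and_logged(self):
        df = self._table(seed=1)
        y = df["y"].to_numpy()
        df.loc[5, "y"] = y.mean() + 6 * y.std()
        res = HierarchicalRhythmModel(df, "y").fit()
        assert res.excluded_ids == ["sim_005"]
        assert res.n == len(df) - 1
    def test_interaction_trimmed_under_null(self):
        hits = [HierarchicalRhythmModel(self._table(seed=s), "y").fit().interaction_retained
                for s in range(15)]
        assert np.mean(hits) <= 0.4
    def test_recovers_planted_coefficient(self):
        res = HierarchicalRhythmModel(self._table(seed=3, beta_is=-3.0), "y").fit()
        lo, hi = res.conf_int().loc["IS"]
        assert lo <= -3.0 <= hi
    def test_transforms_and_summary(self):
        df = self._table(seed=4)
        df["y"] = np.exp(df["y"] / 3.0)
        res = HierarchicalRhythmModel(df, "y", transform="log").fit()
        assert res.transform == "log"
        assert 0.0 <= res.rsquared <= 1.0
        summ = res.summary()
        assert {"coef", "p", "p_holm"} <= set(summ.columns)
        family = summ["p_holm"].dropna().index
        assert (summ.loc[family, "p_holm"] >= summ.loc[family, "p"] - 1e-12).all()
    def test_rank_deficient_design_named(self):
        df = self._table(seed=5)
        df["SE"] = 2.0 * df["IS"]  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            HierarchicalRhythmModel(df, "y").fit()
    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="fewer than 10"):
            HierarchicalRhythmModel(self._table(seed=6, n=8), "y").fit()
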