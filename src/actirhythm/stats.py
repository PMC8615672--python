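"""Inferential protocol for cohort rhythm studies.

Two model families, organised statsmodels-style (a model object built from
a DataFrame whose ``fit()`` returns a results object with a ``summary()``):

* :class:`PermutationAnova` — factorial (group x age-group) ANOVA with
  Freedman-Lane permutation of reduced-model residuals and Type-II sums of
  squares; a Shapiro-Wilk gate on the cell-means residuals switches
  non-normal outcomes to per-factor Kruskal-Wallis tests.
* :class:`HierarchicalRhythmModel` — ordinary least squares of a cognitive
  outcome on a rhythm predictor (interdaily stability by default) plus the
  covariates sleep efficiency, age, gender and number of full weekend days
  recorded, with optional outcome transformation, >3 SD outlier exclusion,
  and a forward step adding the predictor x age interaction that is kept
  only if its p-value is at most 0.10 or it significantly improves R^2.

Families of p-values are controlled with step-down Holm correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "holm_correct",
    "kruskal_wallis_per_factor",
    "residual_normality_gate",
    "PermutationAnova",
    "PermutationAnovaResults",
    "HierarchicalRhythmModel",
    "HierarchicalModelResults",
]


def holm_correct(pvals: Sequence[float]) -> np.ndarray:
    """Step-down Holm-corrected p-values (order-invariant, monotone)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def kruskal_wallis_per_factor(
    data: pd.DataFrame, outcome: str, factor: str
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H (chi-square) across one factor's levels."""
    groups = [g[outcome].dropna().to_numpy() for _, g in data.groupby(factor, observed=True)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError(f"factor {factor!r} needs at least two non-empty levels")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:  # identical values: H is 0 by convention
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)


def _cell_residuals(data: pd.DataFrame, outcome: str, factors: Sequence[str]) -> np.ndarray:
    cells = data.groupby(list(factors), observed=True)[outcome]
    return (data[outcome] - cells.transform("mean")).to_numpy()


def residual_normality_gate(
    data: pd.DataFrame,
    outcome: str,
    factors: Sequence[str],
    alpha: float = 0.05,
) -> str:
    """Choose the test family from the normality of cell-means residuals.

    Returns ``"permutation"`` when a Shapiro-Wilk test on the residuals of
    the factorial cell-means model does not reject normality at ``alpha``,
    else ``"kruskal_wallis"``.
    """
    sub = data.dropna(subset=[outcome])
    resid = _cell_residuals(sub, outcome, factors)
    if resid.size < 3:
        raise ValueError("need at least 3 residuals for the normality gate")
    if np.ptp(resid) == 0:
        raise ValueError("degenerate outcome: residuals are constant")
    _, p = scipy.stats.shapiro(resid)
    return "permutation" if p >= alpha else "kruskal_wallis"


# ---------------------------------------------------------------------------
# permutation ANOVA


def _dummies(col: pd.Series) -> np.ndarray:
    """Drop-first indicator coding of a categorical column."""
    d = pd.get_dummies(col.astype("category"), drop_first=True)
    return d.to_numpy(dtype=float)


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal-projection (hat) matrix onto col(X) and its rank."""
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


@dataclass
class PermutationAnovaResults:
    """Per-term F statistics and permutation p-values.

    ``pvalues_holm`` is empty until a family correction is applied across
    outcomes (see :func:`apply_holm_family` in the pipeline module).
    """

    outcome: str
    terms: list[str]
    statistics: dict[str, float]
    pvalues: dict[str, float]
    dfs: dict[str, tuple[int, int]]
    method: str
    n_perm: int
    seed: int | None
    n_obs: int
    pvalues_holm: dict[str, float] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            rows.append(
                {
                    "outcome": self.outcome,
                    "term": t,
                    "statistic": self.statistics[t],
                    "df": self.dfs.get(t, (np.nan, np.nan))[0],
                    "p": self.pvalues[t],
                    "p_holm": self.pvalues_holm.get(t, np.nan),
                    "method": self.method,
                }
            )
        return pd.DataFrame(rows)


class PermutationAnova:
    """Factorial permutation ANOVA (Freedman-Lane, Type-II sums of squares).

    Parameters
    ----------
    data : DataFrame
        One row per participant.
    outcome : str
        Numeric outcome column.
    factors : sequence of str
        One or two categorical factor columns; with two, the interaction
        term is included.

    Notes
    -----
    For each term the observed F uses the Type-II decomposition (the term's
    sum of squares is its improvement over the model containing all other
    terms at the same or lower order) with the residual mean square of the
    full model.  The null distribution permutes the residuals of the
    term's reduced model and recomputes F on the reconstructed outcome
    (Freedman-Lane), so nuisance effects are held fixed.  The permutation
    p-value is ``(1 + #{F* >= F}) / (1 + n_perm)``.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, factors: Sequence[str]):
        if not 1 <= len(factors) <= 2:
            raise ValueError("one or two factors supported")
        self.outcome = outcome
        self.factors = list(factors)
        self.data = data.dropna(subset=[outcome, *self.factors]).reset_index(drop=True)
        for f in self.factors:
            if self.data[f].nunique() < 2:
                raise ValueError(f"factor {f!r} has fewer than two observed levels")
        self._build_design()

    def _build_design(self) -> None:
        df = self.data
        n = len(df)
        intercept = np.ones((n, 1))
        blocks: dict[str, np.ndarray] = {}
        for f in self.factors:
            blocks[f] = _dummies(df[f])
        self.terms = list(self.factors)
        if len(self.factors) == 2:
            a, b = self.factors
            inter = np.einsum("ij,ik->ijk", blocks[a], blocks[b]).reshape(n, -1)
            # drop empty-cell columns so the design stays full rank
            nonzero = inter.any(axis=0)
            inter = inter[:, nonzero]
            name = f"{a}:{b}"
            if inter.shape[1] > 0:
                blocks[name] = inter
                self.terms.append(name)
        self._intercept = intercept
        self._blocks = blocks
        self._y = df[self.outcome].to_numpy(dtype=float)
        X_all = np.hstack([intercept, *[blocks[t] for t in self.terms]])
        self._H_all, self._rank_all = _hat(X_all)

    def _design_without(self, term: str) -> np.ndarray:
        a_b = [t for t in self.terms if t != term]
        if ":" not in term and len(self.factors) == 2:
            # Type-II: main effects are tested ignoring the interaction
            a_b = [t for t in a_b if ":" not in t]
        return np.hstack([self._intercept, *[self._blocks[t] for t in a_b]]) if a_b else self._intercept

    def fit(self, n_perm: int = 9999, seed: int | None = 0) -> PermutationAnovaResults:
        """Run the permutation test for every term; deterministic given seed."""
        if n_perm < 1:
            raise ValueError("n_perm must be positive")
        rng = np.random.default_rng(seed)
        y = self._y
        n = y.size
        if np.ptp(y) == 0:  # no variation at all: every term has F = 0, p = 1
            dfs = {t: (self._blocks[t].shape[1], n - self._rank_all) for t in self.terms}
            return PermutationAnovaResults(
                outcome=self.outcome, terms=list(self.terms),
                statistics={t: 0.0 for t in self.terms},
                pvalues={t: 1.0 for t in self.terms}, dfs=dfs,
                method="permutation", n_perm=n_perm, seed=seed, n_obs=n)
        df_err = n - self._rank_all
        stats: dict[str, float] = {}
        pvals: dict[str, float] = {}
        dfs: dict[str, tuple[int, int]] = {}
        for term in self.terms:
            Xr = self._design_without(term)
            Hr, rank_r = _hat(Xr)
            Xf = np.hstack([Xr, self._blocks[term]])
            Hf, rank_f = _hat(Xf)
            df_t = rank_f - rank_r
            if df_t == 0:
                continue

            def f_stat(Y: np.ndarray) -> np.ndarray:
                # Y: (n, m) columns of outcomes
                rss_r = ((Y - Hr @ Y) ** 2).sum(axis=0)
                rss_f = ((Y - Hf @ Y) ** 2).sum(axis=0)
                sse = ((Y - self._H_all @ Y) ** 2).sum(axis=0)
                denom = np.where(sse > 0, sse / df_err, np.inf)
                return (rss_r - rss_f) / df_t / denom

            f_obs = float(f_stat(y[:, None])[0])
            fitted_r = Hr @ y
            e = y - fitted_r
            perms = np.argsort(rng.random((n_perm, n)), axis=1)
            Ystar = fitted_r[:, None] + e[perms].T
            f_null = f_stat(Ystar)
            p = (1.0 + np.count_nonzero(f_null >= f_obs)) / (1.0 + n_perm)
            stats[term] = f_obs
            pvals[term] = float(p)
            dfs[term] = (df_t, df_err)
        return PermutationAnovaResults(
            outcome=self.outcome,
            terms=[t for t in self.terms if t in stats],
            statistics=stats,
            pvalues=pvals,
            dfs=dfs,
            method="permutation",
            n_perm=n_perm,
            seed=seed,
            n_obs=n,
        )


def anova_with_gate(
    data: pd.DataFrame,
    outcome: str,
    factors: Sequence[str],
    n_perm: int = 9999,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> PermutationAnovaResults:
    """Shapiro-gated test: permutation ANOVA for normal residuals, else
    per-factor Kruskal-Wallis (no interaction term in the rank branch)."""
    sub = data.dropna(subset=[outcome, *factors])
    method = residual_normality_gate(sub, outcome, factors, alpha=alpha)
    if method == "permutation":
        return PermutationAnova(sub, outcome, factors).fit(n_perm=n_perm, seed=seed)
    stats: dict[str, float] = {}
    pvals: dict[str, float] = {}
    dfs: dict[str, tuple[int, int]] = {}
    for f in factors:
        h, p = kruskal_wallis_per_factor(sub, outcome, f)
        stats[f] = h
        pvals[f] = p
        dfs[f] = (sub[f].nunique() - 1, 0)
    return PermutationAnovaResults(
        outcome=outcome,
        terms=list(factors),
        statistics=stats,
        pvalues=pvals,
        dfs=dfs,
        method="kruskal_wallis",
        n_perm=0,
        seed=seed,
        n_obs=len(sub),
    )


# ---------------------------------------------------------------------------
# hierarchical linear models


@dataclass
class HierarchicalModelResults:
    """Final-step OLS results plus the bookkeeping of the modelling protocol."""

    outcome: str
    transform: str
    n: int
    excluded_ids: list
    params: pd.Series
    pvalues: pd.Series
    pvalues_holm: pd.Series
    rsquared: float
    fvalue: float
    df_model: int
    df_resid: int
    interaction_retained: bool
    sm_results: object  # statsmodels RegressionResults

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.sm_results.conf_int(alpha)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "coef": self.params,
                "p": self.pvalues,
                "p_holm": self.pvalues_holm,
            }
        )
        out.attrs["outcome"] = self.outcome
        out.attrs["rsquared"] = self.rsquared
        out.attrs["n"] = self.n
        return out


_TRANSFORMS = {
    "none": lambda y: y,
    "log": np.log,
    "sqrt": np.sqrt,
}


class HierarchicalRhythmModel:
    """Forward-stepwise OLS of a cognitive outcome on a rhythm predictor.

    Step 1 enters the main effects (predictor + covariates); step 2 adds a
    predictor x age interaction; step 3 trims the interaction unless its
    p-value is at most ``interaction_alpha`` (0.10) or a nested-model
    F-test (alpha 0.05) shows it contributes to the multiple R^2.  Outcome
    values more than ``outlier_sd`` standard deviations from the mean (on
    the transformed scale) are excluded first, and their ids recorded.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        predictor: str = "IS",
        covariates: Sequence[str] = ("SE", "age", "gender", "weekend_days"),
        extra_covariates: Sequence[str] = (),
        transform: str = "none",
        interaction_alpha: float = 0.10,
        nested_alpha: float = 0.05,
        outlier_sd: float = 3.0,
        id_col: str = "participant_id",
    ):
        if transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {transform!r}")
        self.data = data
        self.outcome = outcome
        self.predictor = predictor
        self.covariates = list(covariates)
        self.extra_covariates = list(extra_covariates)
        self.transform = transform
        self.interaction_alpha = interaction_alpha
        self.nested_alpha = nested_alpha
        self.outlier_sd = outlier_sd
        self.id_col = id_col

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, **kwargs):
        return cls(data, outcome, **kwargs)

    def _design(self, df: pd.DataFrame, interaction: bool) -> pd.DataFrame:
        X = pd.DataFrame(index=df.index)
        X[self.predictor] = df[self.predictor].astype(float)
        for c in self.covariates + self.extra_covariates:
            if df[c].dtype == object or str(df[c].dtype) == "category":
                d = pd.get_dummies(df[c], drop_first=True, prefix=c)
                for col in d.columns:
                    X[col] = d[col].astype(float)
            else:
                X[c] = df[c].astype(float)
        if interaction:
            X[f"{self.predictor}:age"] = df[self.predictor].astype(float) * df["age"].astype(float)
        X = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
        if rank < X.shape[1]:
            corr = X.drop(columns="const").corr().abs()
            np.fill_diagonal(corr.values, 0)
            pair = corr.stack().idxmax()
            raise ValueError(f"rank-deficient design; near-collinear terms: {pair}")
        return X

    def fit(self) -> HierarchicalModelResults:
        cols = [self.outcome, self.predictor, "age"] + self.covariates + self.extra_covariates
        cols = list(dict.fromkeys(c for c in cols if c in self.data.columns))
        df = self.data.dropna(subset=cols).copy()
        if len(df) < 10:
            raise ValueError(f"outcome {self.outcome!r}: fewer than 10 complete rows")
        y = _TRANSFORMS[self.transform](df[self.outcome].astype(float))
        if not np.all(np.isfinite(y)):
            raise ValueError(f"transform {self.transform!r} produced non-finite outcomes")
        mu, sd = y.mean(), y.std(ddof=1)
        keep = (y - mu).abs() <= self.outlier_sd * sd if sd > 0 else np.ones(len(y), bool)
        excluded = (
            df.loc[~keep, self.id_col].tolist() if self.id_col in df.columns
            else list(df.index[~keep])
        )
        df, y = df[keep], y[keep]

        X_main = self._design(df, interaction=False)
        main = sm.OLS(y, X_main.astype(float)).fit()
        X_full = self._design(df, interaction=True)
        full = sm.OLS(y, X_full.astype(float)).fit()
        p_int = float(full.pvalues[f"{self.predictor}:age"])
        # nested-model F for the interaction's contribution to R^2
        f_p = float(full.compare_f_test(main)[1])
        retained = (p_int <= self.interaction_alpha) or (f_p <= self.nested_alpha)
        res = full if retained else main
        p_family = res.pvalues.drop("const", errors="ignore")
        holm = pd.Series(holm_correct(p_family.to_numpy()), index=p_family.index)
        return HierarchicalModelResults(
            outcome=self.outcome,
            transform=self.transform,
            n=int(res.nobs),
            excluded_ids=excluded,
            params=res.params,
            pvalues=res.pvalues,
            pvalues_holm=holm,
            rsquared=float(res.rsquared),
            fvalue=float(res.fvalue),
            df_model=int(res.df_model),
            df_resid=int(res.df_resid),
            interaction_retained=retained,
            sm_results=res,
        )
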