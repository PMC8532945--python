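"""Linear (mixed) models for the two utilization responses.

Model 1 -- squares visited per hour, one record per horse-day:

    y = mu + breed + sex + day + b*age + animal(breed) + e

with ``animal`` a zero-mean random intercept (variance sigma_a^2) nested
in breed (each animal has one breed, so a plain per-animal intercept
realises the nesting) and residual variance sigma_e^2.  Estimation is
REML for final inference; fixed-effect structures are compared on
maximum-likelihood fits with AICc alongside BIC, added forward one term
at a time.

Model 2 -- per-square daily usage frequency:

    y = mu + day + location + e

an additive two-way fixed-effects model fit by OLS on visited
(square, day) rows.

Least-square means are marginal means at equal factor-level weights with
covariates at their observed means (the classical LSMEANS convention);
pairwise
LSM differences use Bonferroni-adjusted p-values with a containment-style
denominator df (nobs - rank).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

ALPHA = 0.05


class RankDeficiencyError(ValueError):
    """The design is singular; the message names the aliased term."""


class AICcUndefinedError(ValueError):
    """AICc is undefined: n <= k + 1 for the candidate model."""


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignInfo:
    """Bookkeeping of a treatment-coded design with intercept."""

    terms: list[str]
    cat_levels: dict[str, list] = field(default_factory=dict)
    num_means: dict[str, float] = field(default_factory=dict)
    names: list[str] = field(default_factory=list)
    term_cols: dict[str, list[int]] = field(default_factory=dict)


def build_design(df: pd.DataFrame, terms: list[str]
                 ) -> tuple[np.ndarray, DesignInfo]:
    """Intercept + treatment-coded dummies / centered-as-is covariates.

    A term whose column has a numeric dtype is a covariate; anything else
    is categorical with its first (sorted) level as reference.
    """
    info = DesignInfo(terms=list(terms))
    cols = [np.ones(len(df))]
    info.names = ["Intercept"]
    for t in terms:
        v = df[t]
        if pd.api.types.is_numeric_dtype(v):
            info.num_means[t] = float(v.mean())
            info.term_cols[t] = [len(info.names)]
            info.names.append(t)
            cols.append(v.to_numpy(dtype=float))
        else:
            levels = sorted(v.astype(str).unique())
            info.cat_levels[t] = levels
            idx = []
            vv = v.astype(str).to_numpy()
            for lev in levels[1:]:
                idx.append(len(info.names))
                info.names.append(f"{t}[{lev}]")
                cols.append((vv == lev).astype(float))
            info.term_cols[t] = idx
    X = np.column_stack(cols)
    return X, info


def check_full_rank(X: np.ndarray, info: DesignInfo) -> None:
    """Raise :class:`RankDeficiencyError` naming the first aliased term."""
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    used = [0]
    rank = 1
    for t in info.terms:
        cand = used + info.term_cols[t]
        r = np.linalg.matrix_rank(X[:, cand])
        if r < rank + len(info.term_cols[t]):
            raise RankDeficiencyError(
                f"design is singular: term '{t}' is aliased with preceding terms")
        used, rank = cand, r
    raise RankDeficiencyError("design is singular")


def lsm_rows(info: DesignInfo, factor: str) -> tuple[list, np.ndarray]:
    """Contrast rows producing the LSM of each level of ``factor``.

    Equal weights over the levels of every other categorical term;
    covariates at their observed means.
    """
    if factor not in info.cat_levels:
        raise ValueError(f"'{factor}' is not a categorical term of the fit")
    levels = info.cat_levels[factor]
    p = len(info.names)
    L = np.zeros((len(levels), p))
    L[:, 0] = 1.0
    for t in info.terms:
        if t == factor:
            for i, lev in enumerate(levels[1:]):
                L[i + 1, info.term_cols[t][i]] = 1.0
        elif t in info.cat_levels:
            k = len(info.cat_levels[t])
            for c in info.term_cols[t]:
                L[:, c] = 1.0 / k
        else:
            L[:, info.term_cols[t]] = info.num_means[t]
    return levels, L


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, variance components, criteria and diagnostics of one fit."""

    params: pd.Series
    cov_fe: np.ndarray
    info: DesignInfo
    nobs: int
    llf: float
    k_params: int                 # fixed effects + variance components
    reml: bool
    sigma_e2: float
    sigma_a2: float | None = None          # mixed fits only
    blups: dict[int, float] = field(default_factory=dict)
    residuals: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def aicc(self) -> float:
        n, k = self.nobs, self.k_params
        if n - k - 1 <= 0:
            raise AICcUndefinedError(
                f"AICc undefined: n={n} <= k+1={k + 1}")
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.nobs)

    @property
    def ddf(self) -> int:
        """Containment-style denominator df for LSM t tests."""
        return max(self.nobs - len(self.params), 1)

    def coef(self, name: str) -> tuple[float, float, float]:
        """(estimate, SE, p) of one design column, e.g. the age slope."""
        j = self.info.names.index(name)
        est = float(self.params.iloc[j])
        se = float(np.sqrt(self.cov_fe[j, j]))
        p = 2.0 * stats.t.sf(abs(est / se), self.ddf)
        return est, se, p

    def term_pvalue(self, term: str) -> float:
        """Wald test of all of a term's coefficients jointly being zero."""
        idx = self.info.term_cols[term]
        b = self.params.to_numpy()[idx]
        C = self.cov_fe[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(C, b))
        q = len(idx)
        fstat = stat / q
        return float(stats.f.sf(fstat, q, self.ddf))

    def lsm(self, factor: str) -> pd.DataFrame:
        levels, L = lsm_rows(self.info, factor)
        est = L @ self.params.to_numpy()
        se = np.sqrt(np.einsum("ij,jk,ik->i", L, self.cov_fe, L))
        return pd.DataFrame({"level": levels, "lsm": est, "se": se})

    def excess_kurtosis(self) -> float:
        return float(stats.kurtosis(self.residuals, fisher=True))


# ---------------------------------------------------------------------------
# model 1: mixed model
# ---------------------------------------------------------------------------

MODEL1_TERMS = ("breed_class", "sex", "day", "age")


def prepare_model1_frame(usage: pd.DataFrame, metas: pd.DataFrame) -> pd.DataFrame:
    """Join usage rows with animal metadata; keep included days only."""
    df = usage.loc[usage["included"]] if "included" in usage else usage
    df = df.merge(metas, on="horse_id", validate="many_to_one")
    df = df.copy()
    df["day"] = df["day"].astype(int).astype(str).str.zfill(3)
    return df.reset_index(drop=True)


def _fit_mixed(y, X, info, groups, reml):
    check_full_rank(X, info)
    Xdf = pd.DataFrame(X, columns=info.names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(np.asarray(y, dtype=float), Xdf, groups=np.asarray(groups))
        res = None
        err = None
        # the boundary sigma_a^2 -> 0 can break individual optimizers or
        # yield a degenerate (infinite) log-likelihood
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                cand = model.fit(reml=reml, method=[method], maxiter=500)
            except np.linalg.LinAlgError as e:
                err = e
                continue
            if np.isfinite(cand.llf):
                res = cand
                break
        if res is None:
            raise err if err is not None else np.linalg.LinAlgError(
                "mixed-model likelihood degenerate under all optimizers")
    k_fe = X.shape[1]
    params = pd.Series(res.fe_params.to_numpy(), index=info.names)
    cov_fe = np.asarray(res.cov_params())[:k_fe, :k_fe]
    try:
        blups = {g: float(v.iloc[0]) for g, v in res.random_effects.items()}
    except ValueError:
        # sigma_a^2 estimated at exactly zero: BLUPs are identically zero
        blups = {g: 0.0 for g in np.unique(np.asarray(groups))}
    fitted = X @ params.to_numpy() + np.array(
        [blups[g] for g in np.asarray(groups)])
    return FitResult(
        params=params, cov_fe=cov_fe, info=info, nobs=len(y),
        llf=float(res.llf), k_params=k_fe + 2, reml=reml,
        sigma_e2=float(res.scale), sigma_a2=float(res.cov_re.iloc[0, 0]),
        blups=blups, residuals=np.asarray(y, dtype=float) - fitted,
    )


def fit_model1(usage: pd.DataFrame, metas: pd.DataFrame,
               terms: tuple = MODEL1_TERMS, reml: bool = True) -> FitResult:
    """REML (or ML) fit of the squares-per-hour mixed model.

    Random animal intercept nested in breed; raises
    :class:`RankDeficiencyError` naming the aliased term on singular
    designs (e.g. a single-sex herd with sex in the model).
    """
    df = prepare_model1_frame(usage, metas)
    terms = [t for t in terms]
    for t in terms:
        if not pd.api.types.is_numeric_dtype(df[t]) and df[t].nunique() < 2:
            raise RankDeficiencyError(
                f"design is singular: term '{t}' has a single level "
                "(aliased with the intercept)")
    X, info = build_design(df, terms)
    return _fit_mixed(df["squares_per_hour"], X, info, df["horse_id"], reml)


# ---------------------------------------------------------------------------
# model 2: two-way fixed-effects model
# ---------------------------------------------------------------------------

def fit_model2(frequency_table: pd.DataFrame,
               terms: tuple = ("day", "location")) -> FitResult:
    """OLS fit of the per-square daily usage-frequency model.

    Fit on visited (square, day) rows; location levels with no rows are
    simply absent.  Residual excess kurtosis is exposed for the
    with/without-pasture normality contrast.
    """
    df = frequency_table.copy()
    df["day"] = df["day"].astype(int).astype(str).str.zfill(3)
    X, info = build_design(df, list(terms))
    check_full_rank(X, info)
    y = df["frequency"].to_numpy(dtype=float)
    res = sm.OLS(y, pd.DataFrame(X, columns=info.names)).fit()
    return FitResult(
        params=pd.Series(res.params.to_numpy(), index=info.names),
        cov_fe=np.asarray(res.cov_params()), info=info, nobs=len(y),
        llf=float(res.llf), k_params=X.shape[1] + 1, reml=False,
        sigma_e2=float(res.scale), residuals=np.asarray(res.resid),
    )


# ---------------------------------------------------------------------------
# stepwise selection and LSM comparisons
# ---------------------------------------------------------------------------

def stepwise_select(df: pd.DataFrame, response: str, candidates: list[str],
                    groups: str | None = None,
                    criterion: str = "aicc+bic"
                    ) -> tuple[list[str], FitResult, pd.DataFrame]:
    """Forward stepwise selection of fixed effects by AICc and BIC.

    At each round the candidate with the smallest AICc is added, provided
    it lowers AICc -- and, under the default ``criterion="aicc+bic"``,
    also BIC (using the two criteria in combination keeps the false-
    inclusion rate of null terms low; ``criterion="aicc"`` uses AICc
    alone).  Selection stops when no candidate qualifies.  Fits are
    maximum likelihood (the valid basis for comparing fixed-effect
    structures); ``groups`` keeps the random animal intercept in every
    candidate.  Candidates whose AICc is undefined or whose design is
    singular are refused with a message in the trace.  Returns
    (chosen terms, final ML fit, trace).
    """
    if criterion not in ("aicc+bic", "aicc"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if not candidates:
        raise ValueError("candidate set is empty")

    def _fit(terms):
        X, info = build_design(df, terms) if terms else (
            np.ones((len(df), 1)), DesignInfo(terms=[], names=["Intercept"]))
        if not info.names:
            info.names = ["Intercept"]
        if groups is not None:
            return _fit_mixed(df[response], X, info, df[groups], reml=False)
        check_full_rank(X, info)
        res = sm.OLS(df[response].to_numpy(dtype=float),
                     pd.DataFrame(X, columns=info.names)).fit()
        return FitResult(
            params=pd.Series(res.params.to_numpy(), index=info.names),
            cov_fe=np.asarray(res.cov_params()), info=info, nobs=len(df),
            llf=float(res.llf), k_params=X.shape[1] + 1, reml=False,
            sigma_e2=float(res.scale), residuals=np.asarray(res.resid))

    chosen: list[str] = []
    best = _fit(chosen)
    trace_rows = [{"round": 0, "candidate": "(intercept)", "status": "chosen",
                   "aicc": best.aicc, "bic": best.bic}]
    remaining = list(candidates)
    rnd = 0
    while remaining:
        rnd += 1
        results = {}
        for c in remaining:
            try:
                fit = _fit(chosen + [c])
                row = {"round": rnd, "candidate": c, "status": "tried",
                       "aicc": fit.aicc, "bic": fit.bic}
                results[c] = fit
                trace_rows.append(row)
            except (AICcUndefinedError, RankDeficiencyError) as err:
                trace_rows.append({"round": rnd, "candidate": c,
                                   "status": f"refused: {err}",
                                   "aicc": np.nan, "bic": np.nan})
        if not results:
            break
        winner = min(results, key=lambda c: results[c].aicc)
        if results[winner].aicc >= best.aicc:
            break
        if criterion == "aicc+bic" and results[winner].bic >= best.bic:
            break
        chosen.append(winner)
        best = results[winner]
        remaining.remove(winner)
        for r in trace_rows:
            if r["round"] == rnd and r["candidate"] == winner:
                r["status"] = "chosen"
    return chosen, best, pd.DataFrame(trace_rows)


def lsm_with_bonferroni(fit: FitResult, factor: str
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LSM table plus all pairwise comparisons, Bonferroni adjusted.

    Raw two-sided p-values are multiplied by the number of pairs (capped
    at 1); significance is called at p < 0.05.  A one-level factor yields
    an empty comparison set.
    """
    levels, L = lsm_rows(fit.info, factor)
    beta = fit.params.to_numpy()
    est = L @ beta
    cov = L @ fit.cov_fe @ L.T
    lsm_table = pd.DataFrame({"level": levels, "lsm": est,
                              "se": np.sqrt(np.diag(cov))})
    pairs = list(itertools.combinations(range(len(levels)), 2))
    m = len(pairs)
    if m == 0:
        comp = pd.DataFrame(columns=["level_a", "level_b", "diff", "se",
                                     "t", "p_raw", "p_adj", "significant"])
        return lsm_table, comp
    i = np.array([a for a, _ in pairs])
    j = np.array([b for _, b in pairs])
    diff = est[i] - est[j]
    var = np.diag(cov)[i] + np.diag(cov)[j] - 2.0 * cov[i, j]
    se = np.sqrt(np.maximum(var, 1e-300))
    tval = diff / se
    p_raw = 2.0 * stats.t.sf(np.abs(tval), fit.ddf)
    p_adj = np.minimum(1.0, p_raw * m)
    comp = pd.DataFrame({
        "level_a": [levels[a] for a in i], "level_b": [levels[b] for b in j],
        "diff": diff, "se": se, "t": tval,
        "p_raw": p_raw, "p_adj": p_adj, "significant": p_adj < ALPHA,
    })
    return lsm_table, comp


def n_pairwise(n_levels: int) -> int:
    """Number of pairwise LSM comparisons (and Bonferroni multiplier)."""
    return n_levels * (n_levels - 1) // 2
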