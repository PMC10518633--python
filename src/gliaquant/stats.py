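"""Group-comparison statistics for nested histology and assay designs.

The workhorse is a random-intercept linear mixed model (case or culture
replicate as the grouping factor) fitted by REML, applied to outcomes
first passed through Tukey's ladder-of-powers transformation to tame the
right skew typical of burden and colocalization measurements. Per-term
Wald F tests use a between/within (containment-style) approximate
denominator degrees of freedom, and pairwise group contrasts are adjusted
with the studentized-range (Tukey) family correction. Nesting matters:
stacks from one donor are pseudoreplicates, so effects are tested against
case-level variation, and fold changes are computed on case-level means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TukeyTransform",
    "ModelFitResult",
    "tukey_transform",
    "fit_group_model",
    "pairwise_contrasts",
    "fold_change",
    "correlate",
]

LAMBDA_LADDER = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)


@dataclass
class TukeyTransform:
    """A fitted ladder-of-powers transformation.

    ``transform`` maps x to ``log(x + shift)`` for lambda = 0 and to
    ``((x + shift)**lambda - 1) / lambda`` otherwise — strictly increasing
    for every lambda on the ladder.
    """

    lambda_: float
    shift: float
    values: np.ndarray
    normality_score: float

    def transform(self, x) -> np.ndarray:
        y = np.asarray(x, dtype=float) + self.shift
        if np.any(y <= 0):
            raise ValueError("values out of the transform's positive domain")
        if self.lambda_ == 0.0:
            return np.log(y)
        return (y ** self.lambda_ - 1.0) / self.lambda_


def _normality_score(t: np.ndarray) -> float:
    """Correlation of sample order statistics with normal quantiles."""
    (osm, osr), (_, _, r) = sps.probplot(t, dist="norm", fit=True)
    return float(r)


def tukey_transform(values) -> TukeyTransform:
    """Select the ladder power that best normalises the sample.

    The candidate lambdas are {-2, -1, -1/2, 0 (log), 1/2, 1, 2}; data are
    shifted by ``1e-6 + |min|`` when nonpositive values are present. The
    winner maximises the normal quantile-quantile correlation.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if x.size < 3:
        raise ValueError("need at least 3 values to choose a transformation")
    if np.ptp(x) == 0:
        raise ValueError("constant input has no informative transformation")
    shift = 0.0 if x.min() > 0 else 1e-6 + abs(float(x.min()))
    best = None
    for lam in LAMBDA_LADDER:
        y = x + shift
        t = np.log(y) if lam == 0.0 else (y ** lam - 1.0) / lam
        score = _normality_score(t)
        if best is None or score > best[1]:
            best = (lam, score, t)
    lam, score, t = best
    return TukeyTransform(lambda_=lam, shift=shift, values=t, normality_score=score)


@dataclass
class ModelFitResult:
    """Mixed-model fit summary with approximate F tests and contrasts."""

    params: pd.DataFrame
    anova: pd.DataFrame
    transform: TukeyTransform | None
    converged: bool
    singular: bool
    group_var: float
    n_obs: int
    n_groups: int
    outcome: str
    random_group: str
    _result: object = field(repr=False, default=None)
    _data: pd.DataFrame = field(repr=False, default=None)
    _term_ddf: dict = field(repr=False, default_factory=dict)
    _cov: np.ndarray = field(repr=False, default=None)


def _fe_covariance(res, groups: pd.Series) -> np.ndarray:
    """GLS covariance of the fixed effects at the REML variance estimates.

    Computed directly from ``V_i = sigma^2 I + tau^2 J`` per group, which
    stays well defined when the random-intercept variance sits on the
    boundary (tau^2 = 0), where the optimiser's Hessian-based covariance
    can degenerate.
    """
    s2 = float(res.scale)
    tau2 = float(np.asarray(res.cov_re).ravel()[0])
    X = np.asarray(res.model.exog)
    info = np.zeros((X.shape[1], X.shape[1]))
    codes = pd.Categorical(groups).codes
    for g in np.unique(codes):
        Xi = X[codes == g]
        ni = Xi.shape[0]
        xtx = Xi.T @ Xi
        s = Xi.sum(axis=0)
        shrink = tau2 / (s2 + ni * tau2)
        info += (xtx - shrink * np.outer(s, s)) / s2
    return np.linalg.inv(info)


def _term_column_map(exog_names: list[str], fixed_terms: list[str]) -> dict[str, list[int]]:
    """Map each model term to its design-matrix column indices."""
    out: dict[str, list[int]] = {t: [] for t in fixed_terms}
    for j, name in enumerate(exog_names):
        if name == "Intercept":
            continue
        base = name.split("[")[0]
        for t in fixed_terms:
            if base == t or base == f"C({t})":
                out[t].append(j)
                break
    return out


def fit_group_model(
    table: pd.DataFrame,
    outcome: str,
    fixed_terms: list[str],
    random_group: str,
    transform: bool = True,
) -> ModelFitResult:
    """Random-intercept mixed model with per-term approximate F tests.

    Categorical fixed effects are detected from the column dtype. The
    model is fitted by REML; with zero between-group variance and a
    balanced design the Wald F for a single factor approaches the one-way
    fixed-effects ANOVA F. Non-convergence raises; a boundary (zero)
    random-effect variance is reported via ``singular`` rather than
    hidden. Denominator df follow a between/within containment rule:
    group-level terms are tested against ``n_groups - p_between``,
    within-group terms against ``n_obs - n_groups - p_within``.
    """
    import statsmodels.formula.api as smf

    data = table.copy()
    for col in (outcome, random_group):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from table")
    if data[outcome].isna().any():
        raise ValueError("missing outcome values; exclude them explicitly first")
    if data[random_group].astype(str).str.len().eq(0).any():
        raise ValueError("empty case/replicate ids")
    tt: TukeyTransform | None = None
    ycol = outcome
    if transform:
        tt = tukey_transform(data[outcome].to_numpy())
        ycol = f"__tukey_{outcome}"
        data[ycol] = tt.values
    terms = []
    for t in fixed_terms:
        if t not in data.columns:
            raise ValueError(f"fixed term {t!r} missing from table")
        is_cat = (data[t].dtype == object or data[t].dtype.name == "category"
                  or data[t].dtype == bool)
        terms.append(f"C({t})" if is_cat else t)
    formula = f"{ycol} ~ " + (" + ".join(terms) if terms else "1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data[random_group])
        res = None
        for method in (None, "lbfgs", "powell"):
            try:
                cand = (model.fit(reml=True) if method is None
                        else model.fit(reml=True, method=method))
            except Exception:
                continue
            res = cand
            if cand.converged:
                break
    if res is None:
        raise RuntimeError("mixed model fit failed for every optimiser")
    group_var = float(np.asarray(res.cov_re).ravel()[0])
    resid_var = float(res.scale)
    singular = group_var < 1e-10 * max(resid_var, 1e-300)

    fe = res.fe_params
    k_fe = len(fe)
    cov = _fe_covariance(res, data[random_group])
    exog_names = list(res.model.exog_names)
    params = pd.DataFrame({
        "term": exog_names,
        "estimate": np.asarray(fe),
        "se": np.sqrt(np.diag(cov)),
    })
    params["z"] = params["estimate"] / params["se"]

    groups = data[random_group]
    n_obs = len(data)
    n_groups = groups.nunique()
    col_map = _term_column_map(exog_names, fixed_terms)
    # which terms vary within groups?
    exog = np.asarray(res.model.exog)
    between_terms, within_terms = [], []
    for t, cols in col_map.items():
        if not cols:
            continue
        sub = pd.DataFrame(exog[:, cols])
        varies = (sub.groupby(groups.to_numpy(), sort=False)
                  .nunique().gt(1).any().any())
        (within_terms if varies else between_terms).append(t)
    p_between = 1 + sum(len(col_map[t]) for t in between_terms)
    p_within = sum(len(col_map[t]) for t in within_terms)
    rows = []
    term_ddf = {}
    for t in fixed_terms:
        cols = col_map[t]
        if not cols:
            continue
        L = np.zeros((len(cols), k_fe))
        for i, j in enumerate(cols):
            L[i, j] = 1.0
        est = L @ np.asarray(fe)
        mid = L @ cov @ L.T
        fstat = float(est @ np.linalg.solve(mid, est)) / len(cols)
        if t in between_terms:
            ddf = max(n_groups - p_between, 1)
        else:
            ddf = max(n_obs - n_groups - p_within, 1)
        pval = float(sps.f.sf(fstat, len(cols), ddf))
        term_ddf[t] = ddf
        rows.append({"term": t, "F": fstat, "df_num": len(cols),
                     "df_den": ddf, "p": pval})
    anova = pd.DataFrame(rows, columns=["term", "F", "df_num", "df_den", "p"])
    if not anova.empty:
        params = params.merge(
            pd.DataFrame({"term": exog_names}), on="term", how="right")
    return ModelFitResult(
        params=params, anova=anova, transform=tt, converged=bool(res.converged),
        singular=singular, group_var=group_var, n_obs=n_obs, n_groups=n_groups,
        outcome=outcome, random_group=random_group,
        _result=res, _data=data, _term_ddf=term_ddf, _cov=cov,
    )


def pairwise_contrasts(fit: ModelFitResult, factor: str) -> pd.DataFrame:
    """All level-pair contrasts of a categorical factor, Tukey-adjusted.

    Adjusted p values come from the studentized-range distribution with
    the factor's approximate denominator df; with two levels the family
    has one member and the adjusted p equals the unadjusted one.
    """
    res = fit._result
    data = fit._data
    if factor not in data.columns:
        raise ValueError(f"unknown factor {factor!r}")
    levels = list(pd.unique(data[factor].astype(str)))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels for contrasts")
    exog_names = list(res.model.exog_names)
    fe = np.asarray(res.fe_params)
    k_fe = len(fe)
    cov = fit._cov
    # treatment coding: map each level to its dummy column (baseline -> none)
    col_of: dict[str, int | None] = {lv: None for lv in levels}
    for j, name in enumerate(exog_names):
        for lv in levels:
            if name in (f"C({factor})[T.{lv}]", f"{factor}[T.{lv}]"):
                col_of[lv] = j
    if all(v is None for v in col_of.values()):
        raise ValueError(f"factor {factor!r} not in the fitted model")
    ddf = fit._term_ddf.get(factor, max(fit.n_groups - 2, 1))
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            L = np.zeros(k_fe)
            if col_of[levels[i]] is not None:
                L[col_of[levels[i]]] = 1.0
            if col_of[levels[j]] is not None:
                L[col_of[levels[j]]] -= 1.0
            est = float(L @ fe)
            se = float(np.sqrt(L @ cov @ L))
            tstat = est / se
            q = abs(tstat) * np.sqrt(2.0)
            p_adj = float(np.clip(sps.studentized_range.sf(q, k, ddf), 0.0, 1.0))
            rows.append({
                "level_a": levels[i], "level_b": levels[j],
                "estimate": est, "se": se, "t": tstat, "df": ddf,
                "p_adj": p_adj,
            })
    return pd.DataFrame(rows)


def fold_change(
    case_level_table: pd.DataFrame,
    group_a: str,
    group_b: str,
    outcome: str = "value",
    group_col: str = "group",
    case_col: str = "case_id",
    n_boot: int = 1000,
    seed: int = 0,
    use_median: bool = False,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Ratio of group means of case-level mean outcome, with bootstrap CI.

    Observations are first averaged within each case so pseudoreplicates
    cannot inflate the estimate; the CI is a seeded percentile bootstrap
    over cases within each group. ``use_median`` switches both levels of
    aggregation to medians.
    """
    agg = np.median if use_median else np.mean
    df = case_level_table
    for col in (outcome, group_col, case_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing")
    case_means = (df.groupby([group_col, case_col], observed=True)[outcome]
                  .apply(lambda s: float(agg(s))).reset_index())
    a = case_means.loc[case_means[group_col] == group_a, outcome].to_numpy()
    b = case_means.loc[case_means[group_col] == group_b, outcome].to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    denom = float(agg(b))
    if denom <= 0:
        raise ValueError("reference group mean must be > 0")
    ratio = float(agg(a)) / denom
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = a[rng.integers(0, a.size, a.size)]
        rb = b[rng.integers(0, b.size, b.size)]
        d = float(agg(rb))
        boots[i] = float(agg(ra)) / d if d > 0 else np.nan
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.nanquantile(boots, [alpha, 1.0 - alpha])
    return ratio, (float(lo), float(hi))


def correlate(x, y, method: str = "rank") -> tuple[float, float]:
    """Correlation coefficient and p value (rank = Spearman, linear = Pearson)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined correlation")
    if method == "rank":
        r, p = sps.spearmanr(x, y)
    elif method == "linear":
        r, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
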