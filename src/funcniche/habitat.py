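"""Microhabitat determinants of group counts: screening, GLMs, AICc
model selection, model averaging, and hierarchical partitioning.

Workflow mirrored by :func:`funcniche.pipeline.run_pipeline`:

1. :func:`normality_screen` - Shapiro-Wilk per microhabitat variable.
2. :func:`correlation_screen` - pairwise Spearman (if either variable is
   non-normal) or Pearson correlations; near-collinear pairs
   (|r| >= 0.9, p < .05) are collapsed to one member.
3. :func:`all_subsets` - per-group count GLMs over every predictor
   subset, ranked by small-sample AICc; a single best model is declared
   only when the runner-up trails by more than 2 AICc units.
4. :func:`model_average` - Akaike-weighted full averaging with
   unconditional standard errors (Burnham-Anderson).
5. :func:`hierarchical_partition` - Chevan-Sutherland decomposition of
   the full model's goodness of fit into each predictor's independent
   contribution, by averaging its improvement over all model hierarchies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ENV_VARS",
    "GLMFit",
    "ModelTable",
    "PartitionResult",
    "ScreenResult",
    "aicc",
    "akaike_weights",
    "all_subsets",
    "correlation_screen",
    "fit_glm",
    "hierarchical_partition",
    "model_average",
    "normality_screen",
]

logger = logging.getLogger(__name__)

#: the 11 microhabitat variables measured per transect
ENV_VARS = ["AT", "AH", "SGT", "ST", "SH", "slope", "aspect", "Illu", "RC", "BSC", "CGC"]

#: collinear pairs are collapsed to the ecologically prioritized member
DEFAULT_KEEP_RULES = {frozenset({"SGT", "ST"}): "ST", frozenset({"BSC", "CGC"}): "CGC"}


# ---------------------------------------------------------------- screening

def normality_screen(env: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk normality test for each variable.

    Returns a DataFrame indexed by variable with columns ``W``, ``p`` and
    ``normal`` (p >= alpha).  Constant variables are flagged
    non-testable (``normal`` = NaN).  Requires >= 3 observations.
    """
    if len(env) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    rows = {}
    for col in env.columns:
        x = env[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows[col] = {"W": np.nan, "p": np.nan, "normal": np.nan}
            continue
        w, p = stats.shapiro(x)
        rows[col] = {"W": w, "p": p, "normal": p >= alpha}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class ScreenResult:
    kept: list[str]
    dropped: list[str]
    corr: pd.DataFrame
    pvalues: pd.DataFrame
    method: pd.DataFrame


def correlation_screen(
    env: pd.DataFrame,
    normality: pd.DataFrame | None = None,
    threshold: float = 0.9,
    keep_rules: dict | None = None,
) -> ScreenResult:
    """Collapse near-collinear variable pairs to a single member.

    Each pair is tested with Spearman's rank correlation when either
    member failed the normality screen, Pearson otherwise.  Pairs with
    |r| >= ``threshold`` and p < .05 are collapsed; the surviving member
    is chosen by ``keep_rules`` (a map from the unordered pair to the
    variable to keep) and otherwise the member less correlated with the
    remaining variables is retained.
    """
    if normality is None:
        normality = normality_screen(env)
    if keep_rules is None:
        keep_rules = dict(DEFAULT_KEEP_RULES)
    else:
        keep_rules = {frozenset(k): v for k, v in keep_rules.items()}
        for pair, keep in keep_rules.items():
            unknown = [v for v in set(pair) | {keep} if v not in env.columns]
            if unknown:
                raise ValueError(f"keep_rules name absent variable(s): {unknown}")
            if keep not in pair:
                raise ValueError(f"keep rule for {set(pair)} keeps outside member {keep!r}")

    cols = list(env.columns)
    r_mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p_mat = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    m_mat = pd.DataFrame("", index=cols, columns=cols)
    flagged: list[tuple[float, str, str]] = []
    for a, b in combinations(cols, 2):
        # Spearman unless BOTH members passed the normality screen
        use_spearman = not (normality.loc[a, "normal"] == True  # noqa: E712
                            and normality.loc[b, "normal"] == True)  # noqa: E712
        x, y = env[a].to_numpy(float), env[b].to_numpy(float)
        if use_spearman:
            r, p = stats.spearmanr(x, y)
            method = "spearman"
        else:
            r, p = stats.pearsonr(x, y)
            method = "pearson"
        r_mat.loc[a, b] = r_mat.loc[b, a] = r
        p_mat.loc[a, b] = p_mat.loc[b, a] = p
        m_mat.loc[a, b] = m_mat.loc[b, a] = method
        if abs(r) >= threshold and p < 0.05:
            flagged.append((abs(r), a, b))

    kept = list(cols)
    dropped: list[str] = []
    for _, a, b in sorted(flagged, reverse=True):
        if a not in kept or b not in kept:
            continue  # already resolved through another pair
        rule = keep_rules.get(frozenset({a, b}))
        if rule is not None:
            keep = rule
        else:
            # keep the member less entangled with everything else
            others = [c for c in kept if c not in (a, b)]
            mean_r = {v: r_mat.loc[v, others].abs().mean() if others else 0.0
                      for v in (a, b)}
            keep = min((a, b), key=lambda v: (mean_r[v], v))
            logger.info("correlation_screen: no keep rule for (%s, %s); keeping %s",
                        a, b, keep)
        drop = b if keep == a else a
        kept.remove(drop)
        dropped.append(drop)
    return ScreenResult(kept=kept, dropped=dropped, corr=r_mat, pvalues=p_mat,
                        method=m_mat)


# ------------------------------------------------------------------- GLMs

@dataclass
class GLMFit:
    params: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    loglik: float
    k: int
    deviance: float
    null_deviance: float
    family: str
    converged: bool
    n: int


def _zscore(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant predictor(s): {sd.index[sd == 0].tolist()}")
    return (X - X.mean()) / sd


def fit_glm(
    counts: np.ndarray,
    predictors: pd.DataFrame,
    family: str = "poisson",
    standardize: bool = True,
    min_df: int = 2,
    strict: bool = True,
) -> GLMFit:
    """Fit a count GLM with log link and Wald inference.

    ``family`` is ``"poisson"`` or ``"negbin"`` (negative binomial with
    ML-estimated dispersion; the dispersion parameter counts toward k).
    Predictors are z-scored by default so coefficients are comparable
    across variables.  Requires n >= k + min_df where k is the number of
    estimated parameters; the default margin of 2 keeps AICc defined,
    hierarchical partitioning relaxes it to 1.

    ``strict=False`` accepts boundary solutions whose coefficients did
    not converge but whose deviance did (e.g. a zero count driven to a
    zero fitted rate in a near-saturated model); such fits are fine for
    goodness-of-fit purposes but their Wald SEs are meaningless.
    """
    y = np.asarray(counts, dtype=float)
    X = predictors.copy()
    if len(X) != len(y):
        raise ValueError("counts and predictors disagree in length")
    if standardize and X.shape[1] > 0:
        X = _zscore(X)
    n = len(y)
    design = sm.add_constant(X, has_constant="add")
    k = design.shape[1] + (1 if family == "negbin" else 0)
    if n < k + min_df:
        raise ValueError(f"need n >= k + {min_df} (= {k + min_df}); got n = {n}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "poisson":
            model = sm.GLM(y, design, family=sm.families.Poisson())
            res = model.fit()
        elif family == "negbin":
            model = sm.NegativeBinomial(y, design)
            res = model.fit(disp=0, maxiter=200)
        else:
            raise ValueError(f"unknown family {family!r}")

    converged = bool(getattr(res, "converged", True)
                     if family == "poisson"
                     else res.mle_retvals.get("converged", True))

    def _sane_deviance(r) -> bool:
        dev = float(r.deviance) if family == "poisson" else _nb_deviance(
            y, np.asarray(r.predict()), float(r.params[-1]))
        null = float(r.null_deviance) if family == "poisson" else np.inf
        return np.isfinite(dev) and -1e-6 <= dev <= null * (1 + 1e-8) + 1e-6

    acceptable = converged and np.all(np.isfinite(res.params))
    if not acceptable and not strict and family == "poisson":
        # boundary ML solution (e.g. a zero count driven to rate 0 in a
        # near-saturated model): the deviance limit is well defined even
        # though coefficients diverge.  IRLS can overshoot there, so
        # retry with a gradient optimizer and keep the fit only if its
        # deviance is sane (never worse than the null model).
        if not _sane_deviance(res):
            res = model.fit(method="lbfgs", maxiter=2000, disp=False)
        acceptable = _sane_deviance(res)
    if not acceptable:
        raise RuntimeError(
            f"GLM did not converge (family={family}, predictors="
            f"{list(predictors.columns)}, n={n})"
        )
    params = pd.Series(np.asarray(res.params)[: design.shape[1]],
                       index=design.columns)
    se = pd.Series(np.asarray(res.bse)[: design.shape[1]], index=design.columns)
    z = params / se
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=design.columns)

    if family == "poisson":
        deviance, null_dev = float(res.deviance), float(res.null_deviance)
        loglik = float(res.llf)
    else:
        loglik = float(res.llf)
        mu = np.asarray(res.predict())
        alpha = float(res.params[-1])
        deviance = _nb_deviance(y, mu, alpha)
        null_dev = _nb_deviance(y, np.full(n, y.mean()), alpha)
    return GLMFit(params=params, se=se, z=z, p=pvals, loglik=loglik, k=k,
                  deviance=deviance, null_deviance=null_dev, family=family,
                  converged=converged, n=n)


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = (y + 1.0 / alpha) * np.log((1 + alpha * y) / (1 + alpha * mu))
    return float(2.0 * np.sum(t1 - t2))


def akaike_weights(delta: np.ndarray) -> np.ndarray:
    """Akaike weights exp(-delta/2) / sum, from AICc differences."""
    d = np.asarray(delta, dtype=float)
    w = np.exp(-0.5 * (d - d.min()))
    return w / w.sum()


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n <= k + 1 (n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# -------------------------------------------------------- model selection

@dataclass
class ModelTable:
    """All-subsets GLM comparison ranked by AICc.

    ``table`` has one row per fitted subset with logLik, k, AICc, delta
    and Akaike weight (weights renormalized over converged rows);
    ``best`` is the subset of the top model when its runner-up trails by
    more than 2 AICc units, else None with ``ambiguous=True``.
    """

    table: pd.DataFrame
    fits: dict[tuple, GLMFit]
    best: tuple | None
    ambiguous: bool
    n: int
    family: str


def all_subsets(
    counts: np.ndarray,
    predictors: pd.DataFrame,
    family: str = "poisson",
) -> ModelTable:
    """Fit every predictor subset (including intercept-only), rank by AICc.

    Subsets whose fit fails (non-convergence, or too many parameters for
    the sample size) are flagged, excluded from the Akaike weights, and
    logged.  Limited to 12 predictors (2^p enumeration).
    """
    names = list(predictors.columns)
    p = len(names)
    if p > 12:
        raise ValueError(f"all-subsets enumeration limited to 12 predictors; got {p}")
    y = np.asarray(counts, dtype=float)
    X = _zscore(predictors)

    rows = []
    fits: dict[tuple, GLMFit] = {}
    for size in range(p + 1):
        for subset in combinations(names, size):
            try:
                fit = fit_glm(y, X[list(subset)], family=family, standardize=False)
                crit = aicc(fit.loglik, fit.k, fit.n)
                fits[subset] = fit
                rows.append({"subset": subset, "k": fit.k, "logLik": fit.loglik,
                             "AICc": crit, "status": "ok"})
            except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
                logger.info("all_subsets: subset %s failed: %s", subset, exc)
                rows.append({"subset": subset, "k": len(subset) + 1,
                             "logLik": np.nan, "AICc": np.nan, "status": "failed"})
    table = pd.DataFrame(rows)
    ok = table["status"] == "ok"
    if not ok.any():
        raise RuntimeError("no subset model converged")
    table = pd.concat([table[ok].sort_values("AICc"), table[~ok]], ignore_index=True)
    best_aicc = table.loc[0, "AICc"]
    table["delta"] = table["AICc"] - best_aicc
    table["weight"] = 0.0
    ok_mask = table["status"] == "ok"
    table.loc[ok_mask, "weight"] = akaike_weights(table.loc[ok_mask, "delta"])

    ok_rows = table[table["status"] == "ok"]
    if len(ok_rows) > 1:
        runner_delta = ok_rows["delta"].iloc[1]
        ambiguous = runner_delta <= 2.0
    else:
        ambiguous = False
    best = None if ambiguous else tuple(ok_rows["subset"].iloc[0])
    return ModelTable(table=table, fits=fits, best=best, ambiguous=ambiguous,
                      n=len(y), family=family)


def model_average(model_table: ModelTable, scope: str = "all") -> pd.DataFrame:
    """Akaike-weighted full model average with unconditional SEs.

    ``scope`` selects the model set: ``"all"`` (every converged model),
    ``"delta2"`` (AICc within 2 of the best) or ``"cum95"`` (smallest set
    reaching 95% cumulative weight).  Full averaging: a model that
    excludes a predictor contributes a coefficient of 0 to the average.
    Unconditional SEs follow Burnham-Anderson:
    SE = sum_i w_i * sqrt(SE_i^2 + (beta_i - beta_bar)^2).

    Returns a DataFrame indexed by term with columns coef, se, z, p and
    the selection probability (summed weight of models containing the
    term).
    """
    tab = model_table.table
    ok = tab[tab["status"] == "ok"].copy()
    if scope == "all":
        pass
    elif scope == "delta2":
        ok = ok[ok["delta"] <= 2.0]
    elif scope == "cum95":
        cum = ok["weight"].cumsum()
        ok = ok.loc[: cum.searchsorted(0.95)]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if ok.empty:
        raise ValueError("empty model-averaging scope")
    w = ok["weight"].to_numpy()
    w = w / w.sum()

    terms = ["const"] + [c for c in _all_terms(model_table)]
    out = {}
    for term in terms:
        betas = np.zeros(len(ok))
        ses = np.zeros(len(ok))
        included = np.zeros(len(ok), dtype=bool)
        for i, subset in enumerate(ok["subset"]):
            fit = model_table.fits[tuple(subset)]
            if term in fit.params.index:
                betas[i] = fit.params[term]
                ses[i] = fit.se[term]
                included[i] = True
        beta_bar = float(np.sum(w * betas))
        se_unc = float(np.sum(w * np.sqrt(ses**2 + (betas - beta_bar) ** 2)))
        z = beta_bar / se_unc if se_unc > 0 else np.nan
        out[term] = {
            "coef": beta_bar,
            "se": se_unc,
            "z": z,
            "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
            "sel_prob": float(np.sum(w[included])),
        }
    return pd.DataFrame.from_dict(out, orient="index")


def _all_terms(model_table: ModelTable) -> list[str]:
    seen: list[str] = []
    for subset in model_table.fits:
        for t in subset:
            if t not in seen:
                seen.append(t)
    return seen


# -------------------------------------------- hierarchical partitioning

@dataclass
class PartitionResult:
    """Independent (I) and joint (J) contributions per predictor.

    ``table`` columns: I, I_pct (percent of sum of I), J, total
    (univariate goodness of fit, = I + J).  The independent
    contributions sum exactly to the full model's goodness of fit
    (``full_gof``) - the completeness property of the partition.
    """

    table: pd.DataFrame
    full_gof: float
    gof: str
    family: str


def _gof_all_subsets(y, X, names, family, gof):
    """Goodness of fit for every predictor subset, keyed by frozenset."""
    gofs = {frozenset(): 0.0}
    failures = []
    for size in range(1, len(names) + 1):
        for subset in combinations(names, size):
            try:
                if family == "gaussian":
                    gofs[frozenset(subset)] = _r2(y, X[list(subset)])
                else:
                    fit = fit_glm(y, X[list(subset)], family=family,
                                  standardize=False, min_df=1, strict=False)
                    gofs[frozenset(subset)] = (
                        (fit.null_deviance - fit.deviance) / fit.null_deviance
                    )
            except (ValueError, RuntimeError, np.linalg.LinAlgError):
                failures.append(subset)
    if failures:
        raise RuntimeError(f"hierarchical partition: fits failed for {failures}")
    return gofs


def _r2(y: np.ndarray, X: pd.DataFrame) -> float:
    design = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, design).fit()
    return float(res.rsquared)


def hierarchical_partition(
    counts: np.ndarray,
    predictors: pd.DataFrame,
    family: str = "poisson",
    gof: str | None = None,
) -> PartitionResult:
    """Chevan-Sutherland hierarchical partitioning over all 2^p models.

    The independent contribution of predictor j is its improvement in
    goodness of fit, averaged first over all subsets of a given size that
    exclude j, then across hierarchy levels:

        I_j = (1/p) * sum_h  mean_{|S|=h, j not in S} [gof(S + j) - gof(S)]

    which is exactly the Shapley value of the goodness-of-fit function.
    The joint contribution is J_j = gof({j}) - I_j (it can be negative
    for suppressor structures).  Goodness of fit is the
    deviance-explained fraction for count families and R^2 for
    ``family="gaussian"``.
    """
    names = list(predictors.columns)
    p = len(names)
    if p > 12:
        raise ValueError(f"hierarchical partitioning limited to 12 predictors; got {p}")
    if p == 0:
        raise ValueError("need at least one predictor")
    if gof is None:
        gof = "r2" if family == "gaussian" else "deviance_explained"
    y = np.asarray(counts, dtype=float)
    X = _zscore(predictors) if family != "gaussian" else predictors

    gofs = _gof_all_subsets(y, X, names, family, gof)
    full_gof = gofs[frozenset(names)]

    rows = {}
    for j in names:
        others = [v for v in names if v != j]
        level_means = []
        for h in range(p):
            total = 0.0
            for subset in combinations(others, h):
                s = frozenset(subset)
                total += gofs[s | {j}] - gofs[s]
            level_means.append(total / comb(p - 1, h))
        independent = float(np.mean(level_means))
        rows[j] = {"I": independent, "J": gofs[frozenset({j})] - independent,
                   "total": gofs[frozenset({j})]}
    table = pd.DataFrame.from_dict(rows, orient="index")
    sum_i = table["I"].sum()
    table["I_pct"] = 100.0 * table["I"] / sum_i if sum_i != 0 else np.nan
    table = table[["I", "I_pct", "J", "total"]]
    return PartitionResult(table=table, full_gof=full_gof, gof=gof, family=family)
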