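"""Gaussian GLM fitting, AICc multimodel inference and variance partitioning.

All fits are ordinary Gaussian least-squares models with an intercept.
The information-criterion bookkeeping follows the Gaussian maximum-
likelihood convention: sigma^2 = RSS/n in the likelihood and the
residual variance counted as a free parameter, so

    k    = #terms + 2        (intercept + slopes + sigma^2)
    AIC  = -2 logL + 2k
    AICc = AIC + 2k(k+1)/(n-k-1)

Model uncertainty is handled with the confidence-set (delta AICc <= 2)
model-averaging workflow: Akaike weights, conditional (natural)
coefficient averaging, unconditional standard errors, and relative
importance as summed weights. Hierarchical partitioning decomposes a
full model's R^2 into per-predictor independent contributions by exact
enumeration of all predictor subsets (Chevan & Sutherland).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelFit",
    "ModelSet",
    "PartitionResult",
    "standardize_predictors",
    "fit_gaussian",
    "compare_nested_by_aic",
    "screen_collinearity",
    "all_subsets",
    "confidence_set",
    "average_model",
    "hierarchical_partition",
    "select_buffer",
    "refit_excluding",
]

INTERCEPT = "Intercept"


@dataclass
class ModelFit:
    response: str
    terms: tuple
    params: pd.Series          # includes Intercept
    bse: pd.Series             # OLS standard errors (unbiased sigma^2)
    n: int
    k: int                     # parameters incl. intercept and residual variance
    rss: float
    loglik: float
    aic: float
    aicc: float
    r2: float


@dataclass
class ModelSet:
    """Fits ranked by AICc with deltas and Akaike weights."""

    fits: list
    delta: np.ndarray
    weights: np.ndarray

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "terms": [" + ".join(f.terms) if f.terms else "(intercept)"
                      for f in self.fits],
            "k": [f.k for f in self.fits],
            "aicc": [f.aicc for f in self.fits],
            "delta": self.delta,
            "weight": self.weights,
            "r2": [f.r2 for f in self.fits],
        })


@dataclass
class PartitionResult:
    independent: pd.Series     # I_k, summing to the full-model R^2
    joint: pd.Series           # J_k = R^2({k}) - I_k
    r2_full: float

    @property
    def percentages(self) -> pd.Series:
        total = self.independent.sum()
        return 100.0 * self.independent / total


def standardize_predictors(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center and scale each column to mean 0, sd 1 (sample sd, ddof=1).

    Returns the transformed frame and a (mean, sd) table for
    back-transformation. Constant columns are an error.
    """
    mean = X.mean()
    sd = X.std(ddof=1)
    bad = sd.index[(sd == 0) | ~np.isfinite(sd)]
    if len(bad):
        raise ValueError(f"constant predictor column(s): {list(bad)}")
    return (X - mean) / sd, pd.DataFrame({"mean": mean, "sd": sd})


def _design(X: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(X))]
    cols += [X[t].to_numpy(dtype=float) for t in terms]
    return np.column_stack(cols)


def fit_gaussian(y, X: pd.DataFrame, terms: Optional[Sequence[str]] = None,
                 response: str = "y") -> ModelFit:
    """Least-squares Gaussian fit of ``y`` on the named columns of ``X``.

    Raises on rank-deficient designs (aliased terms are named) and when
    n <= k. A perfect fit (RSS = 0) is reported with infinite
    log-likelihood and AIC/AICc of -inf.
    """
    terms = tuple(terms if terms is not None else X.columns)
    yv = np.asarray(y, dtype=float)
    n = yv.size
    M = _design(X, terms)
    p = M.shape[1]
    k = p + 1  # + residual variance
    if n <= k:
        raise ValueError(f"n = {n} too small for k = {k} parameters")
    rank = np.linalg.matrix_rank(M)
    if rank < p:
        aliased = [t for i, t in enumerate(terms)
                   if np.linalg.matrix_rank(np.delete(M, i + 1, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    beta, _, _, _ = np.linalg.lstsq(M, yv, rcond=None)
    resid = yv - M @ beta
    rss = float(resid @ resid)
    tss = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if rss <= 1e-12 * max(tss, np.finfo(float).tiny):  # numerically perfect fit
        loglik, aic, aicc = math.inf, -math.inf, -math.inf
        bse = pd.Series(0.0, index=[INTERCEPT, *terms])
    else:
        sigma2_ml = rss / n
        loglik = -0.5 * n * (math.log(2 * math.pi * sigma2_ml) + 1.0)
        aic = -2.0 * loglik + 2.0 * k
        aicc = aic + (2.0 * k * (k + 1)) / (n - k - 1) if n - k - 1 > 0 else math.inf
        sigma2 = rss / (n - p)
        cov = sigma2 * np.linalg.inv(M.T @ M)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=[INTERCEPT, *terms])
    params = pd.Series(beta, index=[INTERCEPT, *terms])
    return ModelFit(response=response, terms=terms, params=params, bse=bse,
                    n=n, k=k, rss=rss, loglik=loglik, aic=aic, aicc=aicc, r2=r2)


def compare_nested_by_aic(y, X: pd.DataFrame, base_terms: Sequence[str],
                          extra_terms: Sequence[str],
                          response: str = "y") -> tuple[ModelFit, pd.DataFrame]:
    """Fit a base model and its extension; return the lower-AIC fit.

    Ties go to the smaller model. Used both for the linear-vs-quadratic
    area choice and for checking whether an extra covariate (e.g. patch
    connectivity) earns its place.
    """
    base = fit_gaussian(y, X, base_terms, response)
    full = fit_gaussian(y, X, [*base_terms, *extra_terms], response)
    table = pd.DataFrame({
        "terms": [" + ".join(base.terms), " + ".join(full.terms)],
        "k": [base.k, full.k],
        "aic": [base.aic, full.aic],
        "r2": [base.r2, full.r2],
    })
    chosen = full if full.aic < base.aic else base
    return chosen, table


def screen_collinearity(X: pd.DataFrame, r_max: float = 0.75,
                        vif_max: float = 5.0) -> tuple[list, dict]:
    """Flag highly correlated pairs and prune by variance inflation.

    Pearson pairs with |r| > r_max are reported. Then, iteratively, the
    predictor with the largest VIF (1/(1-R^2) of it regressed on the
    rest) is removed until all VIF <= vif_max. Returns the retained
    column names and a report with flagged pairs, removal order and
    final VIFs.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("need at least two predictors")
    if (X.std(ddof=1) == 0).any():
        raise ValueError("constant predictor")
    corr = X.corr()
    flagged = [(a, b, float(corr.loc[a, b]))
               for a, b in combinations(cols, 2)
               if abs(corr.loc[a, b]) > r_max]

    def vif_of(c, others):
        # plain lstsq R^2: the regressed-on set may itself be collinear
        if not others:
            return 1.0
        yv = X[c].to_numpy(dtype=float)
        M = _design(X, others)
        resid = yv - M @ np.linalg.lstsq(M, yv, rcond=None)[0]
        tss = float(((yv - yv.mean()) ** 2).sum())
        fit_r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
        return math.inf if fit_r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - fit_r2)

    retained = cols[:]
    removed = []
    while len(retained) > 1:
        vifs = {c: vif_of(c, [o for o in retained if o != c]) for c in retained}
        worst = max(vifs, key=lambda c: vifs[c])
        if vifs[worst] <= vif_max:
            break
        retained.remove(worst)
        removed.append((worst, vifs[worst]))
    final_vifs = {c: vif_of(c, [o for o in retained if o != c]) for c in retained}
    report = {"flagged_pairs": flagged, "removed": removed, "vif": final_vifs}
    return retained, report


def all_subsets(y, X: pd.DataFrame, forced_quadratic: Optional[Mapping[str, str]] = None,
                response: str = "y") -> ModelSet:
    """Fit all 2^p additive submodels (intercept-only included), rank by AICc.

    ``forced_quadratic`` maps a squared-term column to its parent linear
    column; the squared term rides along in every subset containing the
    parent (marginality: no quadratic without its linear term), so the
    model count stays 2^p over the linear predictors. Infeasible subsets
    (n <= k) are skipped with a warning entry.
    """
    quad = dict(forced_quadratic or {})
    linear = [c for c in X.columns if c not in quad]
    p = len(linear)
    if p > 20:
        raise ValueError(f"p = {p} too large for exact enumeration")
    by_parent = {parent: sq for sq, parent in quad.items()}
    fits, skipped = [], []
    for h in range(p + 1):
        for subset in combinations(linear, h):
            terms = list(subset)
            for t in subset:
                if t in by_parent:
                    terms.append(by_parent[t])
            try:
                fits.append(fit_gaussian(y, X, terms, response))
            except ValueError as err:
                skipped.append((tuple(terms), str(err)))
    if not fits:
        raise ValueError("no feasible subset models")
    if skipped:
        import warnings
        warnings.warn(f"skipped {len(skipped)} infeasible subset(s)")
    return _rank(fits)


def _rank(fits: Sequence[ModelFit]) -> ModelSet:
    fits = sorted(fits, key=lambda f: (f.aicc, len(f.terms)))
    aicc = np.array([f.aicc for f in fits])
    delta = aicc - aicc[0]
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    return ModelSet(fits=list(fits), delta=delta, weights=w)


def confidence_set(ms: ModelSet, delta_max: float = 2.0) -> ModelSet:
    """Most-plausible models: delta AICc <= delta_max, weights renormalized."""
    keep = [f for f, d in zip(ms.fits, ms.delta) if d <= delta_max]
    return _rank(keep)


def average_model(cs: ModelSet, z: float = 1.96) -> pd.DataFrame:
    """Conditional (natural) model averaging over a confidence set.

    Per term: estimate = weighted mean of coefficients over the models
    containing it (weights renormalized over that subset); unconditional
    se = sum w~_i sqrt(se_i^2 + (b_i - bbar)^2) (Burnham & Anderson);
    CI = estimate +/- z*se; relative importance RI = summed
    confidence-set weights of models containing the term.
    """
    terms: list = [INTERCEPT]
    for f in cs.fits:
        for t in f.terms:
            if t not in terms:
                terms.append(t)
    rows = {}
    for t in terms:
        idx = [i for i, f in enumerate(cs.fits) if t == INTERCEPT or t in f.terms]
        if not idx:
            raise ValueError(f"term {t!r} absent from all models")
        w = cs.weights[idx]
        ri = float(w.sum())
        w = w / w.sum()
        betas = np.array([cs.fits[i].params[t] for i in idx])
        ses = np.array([cs.fits[i].bse[t] for i in idx])
        est = float(w @ betas)
        se = float(w @ np.sqrt(ses ** 2 + (betas - est) ** 2))
        rows[t] = {"estimate": est, "se": se,
                   "ci_low": est - z * se, "ci_high": est + z * se,
                   "ri": ri}
    return pd.DataFrame.from_dict(rows, orient="index")


def hierarchical_partition(y, X: pd.DataFrame) -> PartitionResult:
    """Exact Chevan-Sutherland partition of R^2 over all 2^p subsets.

    The independent effect of predictor k averages, over hierarchy
    levels h and subsets S of size h not containing k, the R^2 gain of
    adding k to S; the independent effects sum exactly to the full-model
    R^2. Joint effect J_k = R^2({k}) - I_k (can be negative under
    suppression).
    """
    cols = list(X.columns)
    p = len(cols)
    if p > 12:
        raise ValueError(f"p = {p} too large for exact enumeration")
    r2 = {frozenset(): 0.0}
    for h in range(1, p + 1):
        for subset in combinations(cols, h):
            r2[frozenset(subset)] = fit_gaussian(y, X, subset).r2
    I = {}
    for k in cols:
        others = [c for c in cols if c != k]
        total = 0.0
        for h in range(0, p):
            gains = [r2[frozenset(S) | {k}] - r2[frozenset(S)]
                     for S in combinations(others, h)]
            total += float(np.mean(gains))
        I[k] = total / p
    independent = pd.Series(I)
    joint = pd.Series({k: r2[frozenset({k})] - I[k] for k in cols})
    return PartitionResult(independent=independent, joint=joint,
                           r2_full=r2[frozenset(cols)])


def select_buffer(responses: Mapping[str, pd.Series],
                  candidate_metrics: Mapping[object, pd.Series]) -> tuple[object, pd.DataFrame]:
    """Pick the buffer radius whose metric best explains the responses.

    For each response x radius, fits the simple one-predictor model and
    tabulates AIC and R^2. The chosen radius has the lowest mean AIC
    rank across responses; ties break to the higher mean R^2.
    """
    radii = list(candidate_metrics)
    if len(radii) < 1:
        raise ValueError("need at least one candidate radius")
    rows = []
    for rname, yser in responses.items():
        for radius in radii:
            metric = candidate_metrics[radius]
            if not yser.index.equals(metric.index):
                metric = metric.reindex(yser.index)
                if metric.isna().any():
                    raise ValueError(f"site ids misaligned for radius {radius!r}")
            Xr = pd.DataFrame({"metric": metric})
            f = fit_gaussian(yser, Xr, ["metric"], response=rname)
            rows.append({"response": rname, "radius": radius,
                         "aic": f.aic, "r2": f.r2})
    table = pd.DataFrame(rows)
    table["aic_rank"] = table.groupby("response")["aic"].rank(method="average")
    means = table.groupby("radius").agg(mean_rank=("aic_rank", "mean"),
                                        mean_r2=("r2", "mean"))
    means = means.sort_values(["mean_rank", "mean_r2"],
                              ascending=[True, False])
    chosen = means.index[0]
    return chosen, table.drop(columns="aic_rank")


def refit_excluding(y: pd.Series, X: pd.DataFrame, excluded_site_ids: Sequence,
                    terms: Optional[Sequence[str]] = None,
                    response: str = "y") -> tuple[ModelFit, ModelFit, float]:
    """Refit after dropping declared outlier sites; report the R^2 change.

    Exclusions are explicit user input (there is no automatic outlier
    detection); the same terms are fitted before and after.
    """
    missing = [s for s in excluded_site_ids if s not in y.index]
    if missing:
        raise KeyError(f"excluded site ids not present: {missing}")
    before = fit_gaussian(y, X, terms, response)
    keep = ~y.index.isin(list(excluded_site_ids))
    after = fit_gaussian(y[keep], X.loc[keep], terms, response)
    return before, after, after.r2 - before.r2
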