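"""Type-level burdens and prediction of immune-checkpoint-blockade approval.

The anti-tumour TIME driver burden (anti-TDB) of a cancer type is the number
of unique drivers whose alterations predict a hotter anti-tumour
microenvironment there (CYS/TIS/ICR with beta > 0 or CPI with beta < 0);
anti-TTB and anti-TOB are its tumour-suppressor and oncogene subsets. The
burden is a property of the cancer type, compared and combined with the
type's median tumour mutational burden (TMB, raw somatic mutation count per
sample) to predict whether checkpoint blockade is approved for that type,
using Bayesian logistic regression (Student-t priors, posterior mode) under
repeated stratified cross-validated ROC evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from timedrivers.core_model import CohortDataset, Role
from timedrivers.ordinal_lasso import Orientation, TimeDriverRecord


def compute_tmb(cohort: CohortDataset, per_mb_divisor: float | None = None) -> tuple[pd.Series, pd.Series]:
    """Per-sample somatic mutation counts and the per-type median.

    All consequence classes count. ``per_mb_divisor`` (e.g. exome megabases)
    optionally rescales to mutations/Mb.
    """
    counts = pd.Series(0, index=pd.Index([s.sample_id for s in cohort.samples],
                                         name="sample_id"), dtype=float)
    for m in cohort.mutations:
        counts[m.sample_id] += 1
    if per_mb_divisor:
        counts = counts / per_mb_divisor
    types = pd.Series({s.sample_id: s.cancer_type for s in cohort.samples})
    med = counts.groupby(types).median().rename("median_tmb")
    return counts.rename("tmb"), med


def compute_burdens(
    records: list[TimeDriverRecord],
    drivers: list,
) -> pd.DataFrame:
    """Per-cancer-type anti-tumour burdens from signed TIME-driver records.

    anti_TDB counts unique genes with at least one anti-tumour record in the
    type; anti_TTB / anti_TOB restrict to tumour suppressors / oncogenes
    (unclassified roles contribute to neither sub-burden).
    """
    role_of = {d.gene_id: d.role for d in drivers}
    anti: dict[str, set[str]] = {}
    for r in records:
        if r.orientation == Orientation.ANTI_TUMOUR:
            anti.setdefault(r.cancer_type, set()).add(r.gene)
    rows = []
    for cancer_type, genes in sorted(anti.items()):
        ttb = sum(role_of.get(g) == Role.TUMOUR_SUPPRESSOR for g in genes)
        tob = sum(role_of.get(g) == Role.ONCOGENE for g in genes)
        rows.append((cancer_type, len(genes), ttb, tob))
    return pd.DataFrame(rows, columns=["cancer_type", "anti_TDB", "anti_TTB",
                                       "anti_TOB"]).set_index("cancer_type")


def correlate_burden_tmb(
    burdens: pd.DataFrame,
    median_tmb: pd.Series,
    exclude: set[str] | None = None,
) -> tuple[float, float]:
    """Pearson correlation of anti-TDB with median TMB across cancer types."""
    types = [t for t in median_tmb.index if not exclude or t not in exclude]
    if len(types) < 3:
        raise ValueError("need >= 3 cancer types after exclusion")
    x = median_tmb.loc[types].to_numpy(float)
    y = burdens["anti_TDB"].reindex(types).fillna(0).to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; correlation undefined")
    r, p = pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Bayesian logistic regression (posterior mode, t priors)


@dataclass
class BayesLogisticFit:
    coef: np.ndarray           # on the original predictor scale
    intercept: float
    coef_std: np.ndarray       # on the standardized scale (prior scale)
    se: np.ndarray             # Wald standard errors (standardized scale)
    p_values: np.ndarray       # approximate, posterior-mode Wald
    x_mean: np.ndarray
    x_sd: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + np.asarray(X, float) @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))


def _t_prior_neglog(beta: np.ndarray, scale: float, df: float = 1.0) -> float:
    # independent Student-t(df, scale) negative log density (constant dropped)
    return float(np.sum((df + 1) / 2 * np.log1p((beta / scale) ** 2 / df)))


def _t_prior_grad(beta: np.ndarray, scale: float, df: float = 1.0) -> np.ndarray:
    return (df + 1) * beta / (df * scale**2 + beta**2)


def _t_prior_hess_diag(beta: np.ndarray, scale: float, df: float = 1.0) -> np.ndarray:
    d = df * scale**2 + beta**2
    return (df + 1) * (d - 2 * beta**2) / d**2


def bayes_logistic_neglogpost(
    params: np.ndarray, X: np.ndarray, y: np.ndarray, prior_scale: float,
) -> float:
    """Negative log posterior on the standardized scale (intercept flat)."""
    eta = params[0] + X @ params[1:]
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    return nll + _t_prior_neglog(params[1:], prior_scale)


def bayes_logistic(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    prior_scale: float = 2.5,
    max_predictors: int = 3,
    min_obs_per_var: int = 10,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> BayesLogisticFit:
    """Posterior-mode logistic fit with heavy-tailed t(1) priors.

    Predictors are standardized internally; the prior (Student-t, df 1,
    scale ``prior_scale``) applies on the standardized coefficients and the
    intercept is unpenalized. Fitting is damped Newton on the penalized
    log-likelihood (penalized IRLS). The variable budget (<= 3 predictors,
    >= 10 observations per predictor) is enforced as a precondition to keep
    the type-level model honest at small n.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p > max_predictors:
        raise ValueError(
            f"{p} predictors exceed the maximum of {max_predictors} "
            "(at most three variables at a time)")
    if n < min_obs_per_var * p:
        raise ValueError(
            f"{n} observations for {p} predictors violates the "
            f">= {min_obs_per_var} observations per variable rule")

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    Z = (X - x_mean) / x_sd
    Z1 = np.column_stack([np.ones(n), Z])

    params = np.zeros(p + 1)
    params[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    for _ in range(max_iter):
        eta = Z1 @ params
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = Z1.T @ (mu - y)
        grad[1:] += _t_prior_grad(params[1:], prior_scale)
        H = (Z1 * w[:, None]).T @ Z1
        hp = _t_prior_hess_diag(params[1:], prior_scale)
        H[1:, 1:] += np.diag(np.maximum(hp, 0.0))  # keep Newton direction descent
        step = np.linalg.solve(H + 1e-12 * np.eye(p + 1), grad)
        # backtracking to guarantee monotone decrease of the objective
        f0 = bayes_logistic_neglogpost(params, Z, y, prior_scale)
        t = 1.0
        while t > 1e-8:
            cand = params - t * step
            if bayes_logistic_neglogpost(cand, Z, y, prior_scale) <= f0:
                break
            t /= 2.0
        params = params - t * step
        if np.max(np.abs(t * step)) < tol:
            break

    eta = Z1 @ params
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = (Z1 * w[:, None]).T @ Z1
    H[1:, 1:] += np.diag(np.maximum(_t_prior_hess_diag(params[1:], prior_scale), 0.0))
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))[1:]
    from scipy.stats import norm
    zstat = params[1:] / se
    pvals = 2.0 * norm.sf(np.abs(zstat))

    coef = params[1:] / x_sd
    intercept = params[0] - float(np.sum(coef * x_mean))
    return BayesLogisticFit(coef=coef, intercept=intercept, coef_std=params[1:],
                            se=se, p_values=pvals, x_mean=x_mean, x_sd=x_sd)


# ---------------------------------------------------------------------------
# repeated cross-validated ROC


@dataclass
class RocResult:
    aucs: np.ndarray
    mean_auc: float
    auc_range95: tuple[float, float]
    curve: pd.DataFrame  # pooled ROC points (fpr, tpr)


def roc_cv(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_repeats: int = 100,
    n_folds: int = 5,
    seed: int = 0,
    prior_scale: float = 2.5,
) -> RocResult:
    """Repeated stratified k-fold cross-validated ROC of a predictor set.

    Each repeat refits the Bayesian logistic model on the training folds and
    scores the held-out fold; the per-repeat AUC pools the out-of-fold
    scores (rank statistic). Reports the AUC distribution and a pooled
    curve.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    # the variable budget applies to the full model; folds are smaller by design
    if X.shape[1] > 3:
        raise ValueError("at most three predictors at a time")
    if len(y) < 10 * X.shape[1]:
        raise ValueError("need >= 10 observations per predictor")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_repeats)
    pooled_scores = np.empty((n_repeats, len(y)))
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        oof = np.empty(len(y))
        for train, test in skf.split(X, y):
            fit = bayes_logistic(X[train], y[train], prior_scale=prior_scale,
                                 min_obs_per_var=0)
            oof[test] = fit.predict_proba(X[test])
        aucs[rep] = roc_auc_score(y, oof)
        pooled_scores[rep] = oof
    mean_scores = pooled_scores.mean(axis=0)
    order = np.argsort(-mean_scores)
    tpr = np.concatenate([[0.0], np.cumsum(y[order]) / max(y.sum(), 1)])
    fpr = np.concatenate([[0.0], np.cumsum(1 - y[order]) / max((1 - y).sum(), 1)])
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    lo, hi = np.quantile(aucs, [0.025, 0.975])
    return RocResult(aucs=aucs, mean_auc=float(aucs.mean()),
                     auc_range95=(float(lo), float(hi)), curve=curve)
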