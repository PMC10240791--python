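"""L1-penalized continuation-ratio ordinal regression with AIC selection.

The ordinal outcome (low < medium < high TIME level) is factorized into
conditional binary logits. In the backward formulation, for each cutpoint
``j = J..2`` every sample with ``y <= j`` contributes a Bernoulli observation
with event ``y == j``:

    logit P(Y = j | Y <= j, x) = alpha_j + x @ beta

with one unpenalized intercept per cutpoint and slopes shared across
cutpoints. The expanded rows form an ordinary logistic design, so the lasso
objective is

    (1/N) * Bernoulli deviance / 2  +  lambda * ||beta||_1

minimized by cyclic coordinate descent on the penalized working least-squares
problem (IRLS middle loop), with warm starts along a geometrically spaced
lambda path from ``lambda_max`` (the smallest lambda that zeroes every slope)
downwards. Model selection is by minimum AIC, counting every non-zero
coefficient (cutpoint intercepts included) as a degree of freedom.

Per-stratum screening: one fit per (cancer type, TIME feature, driver tier),
restricted to samples carrying at least one damaged driver of that tier;
non-zero slopes in the AIC-selected model become signed TIME-driver calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from timedrivers.core_model import CohortDataset, Role, Tier
from timedrivers.time_features import Feature, TimeLevelTable

logger = logging.getLogger(__name__)

_P_EPS = 1e-5  # probability clamp for the IRLS weights


class DegenerateDesignError(ValueError):
    """No informative cutpoint remains after expansion."""


@dataclass
class CrDesign:
    """Expanded continuation-ratio design.

    ``X`` holds the covariate block of the expanded rows; ``events`` the
    Bernoulli outcomes; ``cut_index`` maps each row to its cutpoint (0-based
    over the retained cutpoints, ordered J..2 for the backward formulation).
    """

    X: np.ndarray
    events: np.ndarray
    cut_index: np.ndarray
    sample_index: np.ndarray
    n_cutpoints: int
    n_samples: int
    J: int
    columns: list[str] = field(default_factory=list)


@dataclass
class CrPathFit:
    lambdas: np.ndarray            # decreasing
    alphas: np.ndarray             # (n_lambda, n_cutpoints)
    betas: np.ndarray              # (n_lambda, p)
    loglik: np.ndarray             # unpenalized, expanded data
    df: np.ndarray                 # non-zero coefficients incl. intercepts
    aic: np.ndarray                # 2*df - 2*loglik
    deviance: np.ndarray
    columns: list[str]
    selected_index: int = 0


class Direction(str, Enum):
    MEDIUM_HIGH = "medium_high"    # beta > 0
    MEDIUM_LOW = "medium_low"      # beta < 0


class Orientation(str, Enum):
    ANTI_TUMOUR = "anti_tumour"
    PRO_TUMOUR = "pro_tumour"
    INFILTRATION_ONLY = "infiltration_only"


@dataclass(frozen=True)
class TimeDriverRecord:
    gene: str
    cancer_type: str
    tier: Tier
    feature: Feature
    beta: float

    @property
    def direction(self) -> Direction:
        return Direction.MEDIUM_HIGH if self.beta > 0 else Direction.MEDIUM_LOW

    @property
    def orientation(self) -> Orientation:
        return classify_orientation(self.feature, self.beta)


def classify_orientation(feature: Feature, beta: float) -> Orientation:
    """Anti-/pro-tumour orientation of a signed driver-feature association.

    CYS, TIS and ICR measure anti-tumour immunity, so beta > 0 (alteration
    predicts medium/high levels) is anti-tumour; CPI measures
    cancer-promoting inflammation, so the sign flips. IS measures overall
    infiltration without an anti/pro direction.
    """
    if feature == Feature.IS:
        return Orientation.INFILTRATION_ONLY
    if feature == Feature.CPI:
        return Orientation.PRO_TUMOUR if beta > 0 else Orientation.ANTI_TUMOUR
    return Orientation.ANTI_TUMOUR if beta > 0 else Orientation.PRO_TUMOUR


# ---------------------------------------------------------------------------
# design expansion


def expand_continuation_ratio(
    X: np.ndarray,
    y: np.ndarray,
    J: int,
    direction: str = "backward",
    columns: list[str] | None = None,
) -> CrDesign:
    """Expand an ordinal design into stacked conditional binary rows.

    Backward: cutpoint ``j`` (from J down to 2) receives every sample with
    ``y <= j``, event iff ``y == j``. Forward mirrors it on the reversed
    scale. Cutpoints whose conditional events are constant (a level with no
    samples, or nothing below it) are degenerate and dropped with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y must align on samples")
    if y.min() < 1 or y.max() > J:
        raise ValueError(f"y must lie in 1..{J}")
    if direction == "forward":
        y = J + 1 - y  # forward CR is backward CR on the reversed scale

    rows_X, rows_e, rows_cut, rows_sample = [], [], [], []
    cut = 0
    for j in range(J, 1, -1):
        mask = y <= j
        events = (y[mask] == j).astype(float)
        if mask.sum() == 0 or events.sum() == 0 or events.sum() == mask.sum():
            warnings.warn(
                f"cutpoint {j}: conditional events constant; cutpoint dropped",
                stacklevel=2,
            )
            continue
        rows_X.append(X[mask])
        rows_e.append(events)
        rows_cut.append(np.full(mask.sum(), cut, dtype=int))
        rows_sample.append(np.flatnonzero(mask))
        cut += 1
    if cut == 0:
        raise DegenerateDesignError("all cutpoints degenerate (outcome effectively constant)")
    return CrDesign(
        X=np.vstack(rows_X),
        events=np.concatenate(rows_e),
        cut_index=np.concatenate(rows_cut),
        sample_index=np.concatenate(rows_sample),
        n_cutpoints=cut,
        n_samples=X.shape[0],
        J=J,
        columns=list(columns) if columns is not None else
        [f"x{k}" for k in range(X.shape[1])],
    )


# ---------------------------------------------------------------------------
# fitting


def _linear_predictor(design: CrDesign, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return alpha[design.cut_index] + design.X @ beta


def cr_loglik(design: CrDesign, alpha: np.ndarray, beta: np.ndarray) -> float:
    """Unpenalized log-likelihood of the expanded Bernoulli rows."""
    eta = _linear_predictor(design, alpha, beta)
    return float(np.sum(design.events * eta - np.logaddexp(0.0, eta)))


def _intercept_only(design: CrDesign) -> np.ndarray:
    alpha = np.empty(design.n_cutpoints)
    for c in range(design.n_cutpoints):
        rate = design.events[design.cut_index == c].mean()
        alpha[c] = np.log(rate / (1.0 - rate))
    return alpha


def fit_cr_lasso_path(
    design: CrDesign,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    lambdas: np.ndarray | None = None,
    standardize: bool = False,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> CrPathFit:
    """Fit the lasso path by coordinate descent with warm starts.

    ``standardize=False`` is the default: covariates are binary alteration
    indicators and the screening deliberately penalizes on the natural scale.
    Raises on non-convergence, reporting the offending lambda.
    """
    if standardize:
        sd = design.X.std(axis=0)
        sd[sd == 0] = 1.0
        design = CrDesign(design.X / sd, design.events, design.cut_index,
                          design.sample_index, design.n_cutpoints,
                          design.n_samples, design.J, design.columns)
    X, e, cut = design.X, design.events, design.cut_index
    N, p = X.shape
    cut_masks = [cut == c for c in range(design.n_cutpoints)]

    alpha = _intercept_only(design)
    beta = np.zeros(p)

    if lambdas is None:
        eta0 = alpha[cut]
        p0 = 1.0 / (1.0 + np.exp(-eta0))
        lam_max = np.max(np.abs(X.T @ (e - p0))) / N if p else 1.0
        lam_max = max(lam_max, 1e-10)
        lambdas = lam_max * np.power(lambda_min_ratio, np.linspace(0.0, 1.0, n_lambda))
    lambdas = np.asarray(lambdas, dtype=float)

    n_lam = lambdas.shape[0]
    alphas = np.empty((n_lam, design.n_cutpoints))
    betas = np.empty((n_lam, p))
    loglik = np.empty(n_lam)

    xsq = X ** 2
    for li, lam in enumerate(lambdas):
        for it in range(max_iter):
            eta = alpha[cut] + X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            mu = np.clip(mu, _P_EPS, 1.0 - _P_EPS)
            w = mu * (1.0 - mu)
            z = eta + (e - mu) / w
            # one full cycle of coordinate updates on the working problem
            delta = 0.0
            r = z - eta  # working residual
            for c, m in enumerate(cut_masks):
                wa = w[m]
                new = alpha[c] + np.dot(wa, r[m]) / wa.sum()
                r[m] -= new - alpha[c]
                delta = max(delta, abs(new - alpha[c]))
                alpha[c] = new
            for k in range(p):
                xk = X[:, k]
                wxx = np.dot(w, xsq[:, k])
                if wxx == 0.0:
                    continue
                rho = np.dot(w * xk, r) / N + wxx * beta[k] / N
                new = np.sign(rho) * max(abs(rho) - lam, 0.0) / (wxx / N)
                if new != beta[k]:
                    r -= xk * (new - beta[k])
                    delta = max(delta, abs(new - beta[k]))
                    beta[k] = new
            if delta < tol:
                break
        else:
            raise RuntimeError(
                f"coordinate descent failed to converge at lambda={lam:g} "
                f"after {max_iter} iterations"
            )
        alphas[li] = alpha
        betas[li] = beta
        loglik[li] = cr_loglik(design, alpha, beta)

    # exact zeroing at lambda_max can leave numerically tiny slopes; snap them
    betas[np.abs(betas) < 1e-10] = 0.0
    df = design.n_cutpoints + np.count_nonzero(betas, axis=1)
    aic = 2.0 * df - 2.0 * loglik
    fit = CrPathFit(
        lambdas=lambdas, alphas=alphas, betas=betas, loglik=loglik,
        df=df.astype(float), aic=aic, deviance=-2.0 * loglik,
        columns=design.columns,
    )
    fit.selected_index = int(np.argmin(aic))  # first argmin = largest lambda on ties
    return fit


def select_aic(fit: CrPathFit) -> tuple[int, dict[str, float]]:
    """Index of the minimum-AIC model and its non-zero slope map.

    Ties are broken toward the larger lambda (sparser model).
    """
    idx = int(np.argmin(fit.aic))
    beta = fit.betas[idx]
    nonzero = {fit.columns[k]: float(beta[k]) for k in np.flatnonzero(beta)}
    return idx, nonzero


# ---------------------------------------------------------------------------
# screening driver


@dataclass
class StratumLog:
    cancer_type: str
    feature: Feature
    tier: Tier
    n_samples: int
    n_drivers: int
    fitted: bool
    reason: str = ""
    selected_lambda: float = float("nan")
    df: float = float("nan")


def discover_time_drivers(
    cohort: CohortDataset,
    matrix: "pd.DataFrame | object",
    levels: TimeLevelTable,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> tuple[list[TimeDriverRecord], list[StratumLog]]:
    """Screen every (cancer type, TIME feature, driver tier) stratum.

    ``matrix`` is the binary samples x drivers alteration matrix (an
    :class:`~timedrivers.alteration_calls.AlterationMatrix` or its
    DataFrame). Within a stratum, samples are restricted to those of the
    cancer type with a defined level for the feature and >= 1 damaged driver
    of the tier; drivers altered in no retained sample are dropped from the
    design. Degenerate strata (a single observed level, or no damaged
    samples) are skipped and logged. Returns the signed records and a
    per-stratum fit log.
    """
    mat = getattr(matrix, "indicators", matrix)
    meta = cohort.meta_frame()
    tier_of = {d.gene_id: d.tier for d in cohort.drivers}
    types_of = {d.gene_id: d.cancer_types for d in cohort.drivers}
    records: list[TimeDriverRecord] = []
    logs: list[StratumLog] = []

    for cancer_type in sorted(meta["cancer_type"].unique()):
        type_samples = meta.index[meta["cancer_type"] == cancer_type]
        for feature in Feature:
            lv = levels.levels_for(feature)
            if lv is None:
                continue
            for tier in (Tier.CANONICAL, Tier.CANDIDATE):
                genes = [g for g in mat.columns
                         if tier_of.get(g) == tier
                         and cancer_type in types_of.get(g, ())]
                log = StratumLog(cancer_type, feature, tier, 0, len(genes), False)
                logs.append(log)
                if not genes:
                    log.reason = "no retained drivers of this tier"
                    continue
                sub = mat.loc[mat.index.intersection(type_samples), genes]
                sub = sub.loc[sub.sum(axis=1) >= 1]  # >=1 damaged driver
                sub = sub.loc[sub.index.intersection(lv.dropna().index)]
                log.n_samples = len(sub)
                if len(sub) == 0:
                    log.reason = "no damaged samples with a defined level"
                    continue
                sub = sub.loc[:, sub.sum(axis=0) > 0]
                if sub.shape[1] == 0:
                    log.reason = "no driver altered in the retained samples"
                    continue
                y = lv.loc[sub.index].to_numpy()
                if len(np.unique(y)) < 2:
                    log.reason = "single observed TIME level"
                    continue
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        design = expand_continuation_ratio(
                            sub.to_numpy(float), y, J=3, columns=list(sub.columns)
                        )
                    fit = fit_cr_lasso_path(
                        design, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio
                    )
                except DegenerateDesignError as err:
                    log.reason = str(err)
                    continue
                idx, nonzero = select_aic(fit)
                log.fitted = True
                log.selected_lambda = float(fit.lambdas[idx])
                log.df = float(fit.df[idx])
                for gene, beta in nonzero.items():
                    records.append(TimeDriverRecord(gene, cancer_type, tier, feature, beta))
    return records, logs


def records_frame(records: list[TimeDriverRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene, r.cancer_type, r.tier.value, r.feature.value, r.beta,
          r.direction.value, r.orientation.value) for r in records],
        columns=["gene", "cancer_type", "tier", "feature", "beta",
                 "direction", "orientation"],
    )
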