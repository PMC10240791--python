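"""TIME signature scoring and ordinal discretization.

Five expression-derived features summarize the tumour immune
microenvironment: overall immune infiltration (IS), cytotoxic anti-tumour
infiltration (CYS), immunologic constant of rejection (ICR), tumour
inflammation signature (TIS) and cancer-promoting inflammation (CPI). Each
is computed from a gene list by one of three scoring methods and then
discretized, per cancer type, into ordered low < medium < high levels
(bottom quartile, interquartile band, top quartile) — the ordinal outcome of
the driver screening.

Scoring methods
---------------
``mean_log2``
    Mean of log2(FPKM + 1) over the signature genes (CPI and, by default,
    TIS — the original TIS publication's housekeeping-normalized weighted
    sum is not reproducible from its printed description, so the unweighted
    log-mean stands in; a weight column in the signature file substitutes
    weights when available).
``ssgsea``
    Single-sample gene-set enrichment: genes are ranked per sample (average
    ranks on ties, centered so the weight of a gene is |rank - (n+1)/2|^alpha),
    and the score is the sum of running-sum deviations between the weighted
    in-set and uniform out-of-set cumulative distributions. Rank-based, hence
    invariant under monotone transforms of expression.
``cluster_k``
    K-means on z-scored signature-gene expression; clusters are ordered by
    mean signature z-score and mapped to levels (CYS: six clusters folded
    into three levels; ICR: three clusters mapped by identity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from timedrivers.core_model import CohortDataset, ExpressionMatrix

logger = logging.getLogger(__name__)

LOW, MEDIUM, HIGH = 1, 2, 3


class Feature(str, Enum):
    IS = "IS"
    CYS = "CYS"
    ICR = "ICR"
    TIS = "TIS"
    CPI = "CPI"


class ScoringMethod(str, Enum):
    MEAN_LOG2 = "mean_log2"
    SSGSEA = "ssgsea"
    CLUSTER_K = "cluster_k"


DEFAULT_METHODS: dict[Feature, ScoringMethod] = {
    Feature.IS: ScoringMethod.SSGSEA,
    Feature.CYS: ScoringMethod.CLUSTER_K,
    Feature.ICR: ScoringMethod.CLUSTER_K,
    Feature.TIS: ScoringMethod.MEAN_LOG2,
    Feature.CPI: ScoringMethod.MEAN_LOG2,
}

DEFAULT_K: dict[Feature, int] = {Feature.CYS: 6, Feature.ICR: 3}

# CYS folds six score-ordered clusters into three levels; ICR maps three
# clusters one-to-one.
DEFAULT_LEVEL_MAPS: dict[Feature, dict[int, int]] = {
    Feature.CYS: {1: LOW, 2: LOW, 3: MEDIUM, 4: MEDIUM, 5: HIGH, 6: HIGH},
    Feature.ICR: {1: LOW, 2: MEDIUM, 3: HIGH},
}


class SignatureError(ValueError):
    """A signature cannot be scored on the given expression matrix."""


@dataclass
class SignatureDef:
    feature: Feature
    genes: list[str]
    method: ScoringMethod | None = None
    k: int | None = None
    level_map: dict[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise SignatureError(f"{self.feature.value}: empty gene list")
        if self.method is None:
            self.method = DEFAULT_METHODS[self.feature]
        if self.method == ScoringMethod.CLUSTER_K:
            if self.k is None:
                self.k = DEFAULT_K.get(self.feature, 3)
            if self.level_map is None:
                self.level_map = DEFAULT_LEVEL_MAPS.get(
                    self.feature, {i: min(i, 3) for i in range(1, self.k + 1)}
                )


@dataclass
class TimeLevelTable:
    """Per-sample continuous score and ordinal level for each feature."""

    scores: pd.DataFrame   # samples x features, float
    levels: pd.DataFrame   # samples x features, {1,2,3} or NaN

    def levels_for(self, feature: Feature) -> pd.Series | None:
        if feature.value not in self.levels.columns:
            return None
        return self.levels[feature.value].dropna().astype(int)

    def to_long_frame(self) -> pd.DataFrame:
        s = self.scores.stack().rename("score")
        l = self.levels.stack().rename("level")
        df = pd.concat([s, l], axis=1).reset_index()
        df.columns = ["sample_id", "feature", "score", "level"]
        return df


# ---------------------------------------------------------------------------
# scoring


def _present_genes(expr: ExpressionMatrix, genes: Sequence[str], feature: str) -> list[str]:
    present = [g for g in genes if g in expr.values.index]
    missing = len(genes) - len(present)
    if missing:
        logger.warning("%s: %d of %d signature genes absent from expression",
                       feature, missing, len(genes))
    return present


def score_mean_log2(
    expr: ExpressionMatrix, genes: Sequence[str],
    weights: Mapping[str, float] | None = None, feature: str = "signature",
) -> pd.Series:
    """Mean (optionally weighted) log2(FPKM + 1) over the signature genes."""
    present = _present_genes(expr, genes, feature)
    if not present:
        raise SignatureError(f"{feature}: no signature gene present in the expression matrix")
    block = np.log2(expr.values.loc[present] + 1.0)
    if weights:
        w = np.array([weights.get(g, 1.0) for g in present], dtype=float)
        return pd.Series(block.to_numpy().T @ w / w.sum(), index=expr.samples,
                         name=feature)
    return block.mean(axis=0).rename(feature)


def score_ssgsea(
    expr: ExpressionMatrix, genes: Sequence[str], alpha: float = 0.25,
    feature: str = "signature",
) -> pd.Series:
    """Single-sample enrichment score of the gene set in each sample.

    Genes are ranked per sample with average ranks on ties; each gene's
    weight is |rank - (n+1)/2| ** alpha, which makes the statistic odd under
    reversal of the expression ordering. Walking genes from highest to
    lowest expression, the score is the summed deviation between the
    weighted cumulative in-set distribution and the uniform out-of-set one.
    """
    present = _present_genes(expr, genes, feature)
    if len(present) < 2:
        raise SignatureError(f"{feature}: need >= 2 signature genes present")
    vals = expr.values
    n = vals.shape[0]
    in_set = vals.index.isin(present)
    n_out = n - in_set.sum()
    scores = np.empty(vals.shape[1])
    center = (n + 1) / 2.0
    for j, sample in enumerate(vals.columns):
        x = vals[sample]
        ranks = x.rank(method="average").to_numpy()
        w = np.abs(ranks - center) ** alpha
        order = np.argsort(-x.to_numpy(), kind="stable")
        in_ord = in_set[order]
        w_ord = w[order]
        w_in = w_ord * in_ord
        tot = w_in.sum()
        if tot == 0.0:
            warnings.warn(f"{feature}: constant expression vector in sample "
                          f"{sample}; score set to 0", stacklevel=2)
            scores[j] = 0.0
            continue
        p_in = np.cumsum(w_in) / tot
        p_out = np.cumsum(~in_ord) / n_out
        scores[j] = float(np.sum(p_in - p_out))
    return pd.Series(scores, index=vals.columns, name=feature)


# ---------------------------------------------------------------------------
# discretization


def levels_by_quartile(scores: pd.Series, group_labels: pd.Series) -> pd.Series:
    """Quartile levels within each group (cancer type).

    score <= Q1 -> low, score >= Q3 -> high, else medium, with Q1/Q3 from
    linear-interpolation quantiles; boundary ties fall to the extreme
    groups. Groups of fewer than 4 samples are all medium (warned).
    """
    out = pd.Series(np.nan, index=scores.index, dtype=float)
    for group, idx in scores.groupby(group_labels.reindex(scores.index)).groups.items():
        s = scores.loc[idx]
        if len(s) < 4:
            warnings.warn(f"group {group!r} has {len(s)} (<4) samples; all medium",
                          stacklevel=2)
            out.loc[idx] = MEDIUM
            continue
        q1, q3 = np.quantile(s.to_numpy(), [0.25, 0.75])
        lv = np.full(len(s), MEDIUM, dtype=float)
        # the <=Q1 rule wins when a score satisfies both (fully tied group)
        lv[s.to_numpy() >= q3] = HIGH
        lv[s.to_numpy() <= q1] = LOW
        out.loc[idx] = lv
    return out


def levels_by_cluster(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    k: int,
    level_map: Mapping[int, int],
    seed: int = 0,
    n_init: int = 25,
    feature: str = "signature",
) -> tuple[pd.Series, pd.Series]:
    """K-means levels on z-scored signature expression.

    Returns (score, level): the score is the mean signature z-score (used
    to order clusters from lowest to highest); levels come from
    ``level_map`` applied to the 1-based score-ordered cluster index. Rows
    are sorted by sample id before fitting so the assignment is invariant
    to input sample order.
    """
    present = _present_genes(expr, genes, feature)
    if not present:
        raise SignatureError(f"{feature}: no signature gene present in the expression matrix")
    block = expr.values.loc[present].T  # samples x genes
    n = block.shape[0]
    if n < k:
        raise SignatureError(f"{feature}: {n} samples < k={k} clusters")
    z = (block - block.mean(axis=0)) / block.std(axis=0).replace(0.0, 1.0)
    z = z.sort_index()
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    score = z.mean(axis=1)
    order = (
        pd.Series(score.to_numpy(), index=labels).groupby(level=0).mean().sort_values()
    )
    rank_of = {cluster: r + 1 for r, cluster in enumerate(order.index)}
    level = pd.Series([level_map[rank_of[c]] for c in labels], index=z.index,
                      dtype=float, name=feature)
    return score.reindex(expr.samples).rename(feature), level.reindex(expr.samples)


# ---------------------------------------------------------------------------
# orchestration


def compute_time_levels(
    cohort: CohortDataset,
    signature_defs: Sequence[SignatureDef],
    seed: int = 0,
) -> TimeLevelTable:
    """Score every supplied signature and discretize into ordinal levels.

    Quartile discretization is applied per cancer type for the continuous
    methods; cluster methods carry their own level mapping. Errors from a
    single feature (e.g. all genes absent) propagate.
    """
    meta = cohort.meta_frame()
    types = meta["cancer_type"]
    scores: dict[str, pd.Series] = {}
    levels: dict[str, pd.Series] = {}
    for sig in signature_defs:
        name = sig.feature.value
        if sig.method == ScoringMethod.MEAN_LOG2:
            s = score_mean_log2(cohort.expression, sig.genes, feature=name)
            lv = levels_by_quartile(s, types)
        elif sig.method == ScoringMethod.SSGSEA:
            s = score_ssgsea(cohort.expression, sig.genes, feature=name)
            lv = levels_by_quartile(s, types)
        else:
            s, lv = levels_by_cluster(cohort.expression, sig.genes, sig.k,
                                      sig.level_map, seed=seed, feature=name)
        scores[name] = s
        levels[name] = lv
    return TimeLevelTable(scores=pd.DataFrame(scores), levels=pd.DataFrame(levels))


# ---------------------------------------------------------------------------
# signature files


def read_signature_dir(path: str | Path) -> list[SignatureDef]:
    """Read one ``<FEATURE>.tsv`` per feature (columns gene_id[, weight])."""
    defs = []
    for feature in Feature:
        f = Path(path) / f"{feature.value}.tsv"
        if not f.exists():
            continue
        df = pd.read_csv(f, sep="\t")
        defs.append(SignatureDef(feature=feature, genes=df["gene_id"].tolist()))
    return defs


def write_signature_dir(defs: Sequence[SignatureDef], path: str | Path) -> None:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    for sig in defs:
        pd.DataFrame({"gene_id": sig.genes}).to_csv(
            out / f"{sig.feature.value}.tsv", sep="\t", index=False
        )
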