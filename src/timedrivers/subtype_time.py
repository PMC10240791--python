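"""Copy-number-defined subtype analysis and subtype-level TIME comparisons.

Samples are clustered on their per-locus copy-number states (neutral / low /
high) with agglomerative hierarchical clustering on Euclidean distances; of
the two clusters, the one with the larger mean total state is the CNA-high
subtype. Subtype immune profiles are then compared through: the normalized
sample proportion of a subtype within a TIME level, linear-by-linear
(Mantel-Haenszel) trend tests on ordered level distributions, per-driver
Fisher frequency comparisons with BH correction, and Kruskal-Wallis burden
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2, fisher_exact, kruskal
from statsmodels.stats.multitest import multipletests

NEUTRAL, LOW_STATE, HIGH_STATE = 0, 1, 2


@dataclass
class SubtypeAssignment:
    labels: pd.Series            # sample_id -> subtype label
    method: str


def cna_states_from_gene_cn(
    gene_cn: pd.DataFrame, ploidy: pd.Series
) -> pd.DataFrame:
    """Three-state CNA matrix from gene copy number relative to ploidy.

    ``|cn - round(ploidy)|`` of 0 is neutral, 1 low, >= 2 high — a simple
    per-gene stand-in for externally derived recurrent CNA loci; externally
    produced state matrices can be supplied directly to the clustering.
    """
    mat = gene_cn.pivot_table(index="sample_id", columns="gene_id",
                              values="total_cn", aggfunc="first")
    base = ploidy.reindex(mat.index).round()
    diff = (mat.sub(base, axis=0)).abs()
    states = pd.DataFrame(NEUTRAL, index=mat.index, columns=mat.columns, dtype=int)
    states[diff == 1] = LOW_STATE
    states[diff >= 2] = HIGH_STATE
    return states


def cluster_cna_subtypes(
    states: pd.DataFrame, k: int = 2, linkage_method: str = "average"
) -> SubtypeAssignment:
    """Hierarchical clustering of CNA state rows into k subtypes.

    The tree (Euclidean distance, configurable linkage) is cut at ``k``;
    with k=2 the cluster with the larger mean total state is labelled
    ``CNA_high``, the other ``CNA_low``. Raises when every row is identical
    (no structure to cluster).
    """
    X = states.to_numpy(float)
    if len(states) < k:
        raise ValueError(f"{len(states)} samples < k={k}")
    if (X == X[0]).all():
        raise ValueError("all CNA state rows identical; no structure to cluster")
    Z = linkage(pdist(X, metric="euclidean"), method=linkage_method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    if k == 2:
        burden = pd.Series(X.sum(axis=1), index=raw).groupby(level=0).mean()
        high_cluster = burden.idxmax()
        labels = np.where(raw == high_cluster, "CNA_high", "CNA_low")
    else:
        labels = np.array([f"cluster_{c}" for c in raw])
    return SubtypeAssignment(
        labels=pd.Series(labels, index=states.index, name="subtype"),
        method=f"hierarchical/euclidean/{linkage_method}/k={k}",
    )


def normalized_proportion(n_ij: int, n_i: int, N_j: int, N: int) -> float:
    """Subtype-in-level enrichment ratio (n_ij / n_i) / (N_j / N).

    Values above 1 mean subtype i is over-represented in TIME level j
    relative to the whole cohort.
    """
    if n_i <= 0 or N_j <= 0 or N <= 0:
        raise ValueError("denominator counts must be positive")
    if n_ij > min(n_i, N_j):
        raise ValueError("n_ij cannot exceed its margins")
    return (n_ij / n_i) / (N_j / N)


def normalized_proportion_table(
    levels: pd.Series, groups: pd.Series
) -> pd.DataFrame:
    """Normalized proportion of every (subtype, level) combination."""
    idx = levels.dropna().index.intersection(groups.dropna().index)
    lv, gr = levels.loc[idx], groups.loc[idx]
    N = len(idx)
    out = {}
    for g in sorted(gr.unique()):
        n_i = int((gr == g).sum())
        out[g] = {
            j: normalized_proportion(int(((gr == g) & (lv == j)).sum()), n_i,
                                     int((lv == j).sum()), N)
            for j in sorted(lv.unique())
        }
    return pd.DataFrame(out).T


def compare_level_distributions(
    levels: pd.Series, groups: pd.Series, scores: np.ndarray | None = None
) -> tuple[float, float]:
    """Linear-by-linear (Mantel-Haenszel) trend test on ordered levels.

    Two groups, J ordered levels with integer scores 1..J by default.
    The statistic is (N-1) * r^2 with r the Pearson correlation between the
    group indicator and the level score; p from chi-square with 1 df.
    """
    idx = levels.dropna().index.intersection(groups.dropna().index)
    lv, gr = levels.loc[idx].to_numpy(float), groups.loc[idx]
    labels = sorted(gr.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    if (gr == labels[0]).sum() == 0 or (gr == labels[1]).sum() == 0:
        raise ValueError("empty group")
    x = (gr == labels[1]).to_numpy(float)
    y = lv if scores is None else np.asarray(scores, float)[lv.astype(int) - 1]
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    r = np.corrcoef(x, y)[0, 1]
    stat = (n - 1) * r**2
    return float(stat), float(chi2.sf(stat, df=1))


def compare_driver_frequencies(
    indicators: pd.DataFrame, groups: pd.Series, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-driver 2x2 Fisher comparison of alteration frequency, BH-corrected.

    Returns a frame with per-driver counts, odds ratio, p, FDR and the
    significance flag at ``fdr_threshold``.
    """
    idx = indicators.index.intersection(groups.dropna().index)
    gr = groups.loc[idx]
    labels = sorted(gr.unique())
    if len(labels) != 2 or min((gr == l).sum() for l in labels) == 0:
        raise ValueError("two non-empty groups required")
    a_mask = (gr == labels[0]).to_numpy()
    rows = []
    for gene in indicators.columns:
        v = indicators.loc[idx, gene].to_numpy(int)
        a1, a0 = int(v[a_mask].sum()), int((~v[a_mask].astype(bool)).sum())
        b1, b0 = int(v[~a_mask].sum()), int((~v[~a_mask].astype(bool)).sum())
        odds, p = fisher_exact([[a1, a0], [b1, b0]])
        rows.append((gene, a1, a0, b1, b0, odds, p))
    df = pd.DataFrame(rows, columns=["gene", f"{labels[0]}_alt", f"{labels[0]}_wt",
                                     f"{labels[1]}_alt", f"{labels[1]}_wt",
                                     "odds_ratio", "p"])
    _, fdr, _, _ = multipletests(df["p"], method="fdr_bh")
    df["fdr"] = fdr
    df["significant"] = df["fdr"] < fdr_threshold
    return df.set_index("gene")


def compare_burden_distributions(
    values: pd.Series, groups: pd.Series
) -> tuple[float, float]:
    """Kruskal-Wallis comparison of per-sample burdens across >= 2 groups."""
    idx = values.dropna().index.intersection(groups.dropna().index)
    v, gr = values.loc[idx], groups.loc[idx]
    samples = [v[gr == g].to_numpy(float) for g in sorted(gr.unique())]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    if np.ptp(np.concatenate(samples)) == 0:
        warnings.warn("all burden values identical; H = 0, p = 1", stacklevel=2)
        return 0.0, 1.0
    h, p = kruskal(*samples)
    return float(h), float(p)
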