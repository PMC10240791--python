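"""Cancer cell fraction (CCF) posteriors and clonality calls.

For a mutation observed with ``alt_reads`` of ``depth`` reads in a tumour of
purity rho, local tumour copy number CNt and normal copy number CNn, the
expected variant allele frequency at cancer cell fraction c and mutation
multiplicity m is

    VAF(c) = rho * c * m / (rho * CNt + (1 - rho) * CNn)

The posterior over the CCF grid 0.01..1.00 (step 0.01, uniform prior) is the
normalized binomial likelihood of the observed read counts at each grid
value. The point estimate is the grid argmax; the 95% interval is the
highest-density region (the smallest set of grid points holding 95% of the
mass — contiguous here because the binomial likelihood is log-concave along
the grid), and a mutation is clonal when that interval reaches the top of
the grid (CCF 1). The highest-density region, rather than an equal-tail
interval, is essential at the clonal boundary: a truncated posterior whose
mode sits at CCF 1 spreads its upper tail across many grid points, so the
top grid point alone rarely carries 2.5% of mass and an equal-tail interval
would misclassify a large share of genuinely clonal mutations. A driver is
clonal in a sample when at least one of its damaging mutations is clonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, fisher_exact

from timedrivers.core_model import (
    DAMAGING_MUTATION_CLASSES,
    CohortDataset,
    MutationCall,
)

CCF_GRID = np.round(np.arange(0.01, 1.005, 0.01), 2)  # 100 values


@dataclass
class CcfPosterior:
    grid: np.ndarray
    probs: np.ndarray
    ccf_hat: float
    ci_low: float
    ci_high: float
    clonal: bool
    multiplicity: int


def ccf_posterior(
    alt_reads: int,
    depth: int,
    purity: float,
    tumour_cn: int,
    normal_cn: int = 2,
    multiplicity: int | str = "auto",
) -> CcfPosterior:
    """Grid posterior of the cancer cell fraction for one mutation.

    ``multiplicity="auto"`` estimates the mutated copy count from the
    observed VAF, clamped to [1, tumour_cn]. Expected VAFs above 1 (possible
    for large multiplicities at high CCF) are capped at 1 with a warning.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must lie in (0, 1]")
    if tumour_cn < 1:
        raise ValueError("tumour_cn must be >= 1")

    denom = purity * tumour_cn + (1.0 - purity) * normal_cn
    vaf_obs = alt_reads / depth
    if multiplicity == "auto":
        m = int(np.clip(round(vaf_obs * denom / purity), 1, tumour_cn))
    else:
        m = int(multiplicity)
        if not (1 <= m <= tumour_cn):
            raise ValueError("multiplicity must lie in [1, tumour_cn]")

    vaf = purity * CCF_GRID * m / denom
    if (vaf > 1.0).any():
        warnings.warn("expected VAF exceeds 1 on part of the CCF grid; capped",
                      stacklevel=2)
        vaf = np.minimum(vaf, 1.0)
    like = binom.pmf(alt_reads, depth, vaf)
    total = like.sum()
    if total == 0.0:
        # pathological flat zero likelihood (e.g. underflow); fall back to uniform
        probs = np.full_like(like, 1.0 / like.size)
    else:
        probs = like / total

    ccf_hat = float(CCF_GRID[int(np.argmax(probs))])
    # 95% highest-density region: smallest set of grid points with >= 0.95 mass
    order = np.argsort(-probs, kind="stable")
    k = int(np.searchsorted(np.cumsum(probs[order]), 0.95)) + 1
    region = np.sort(order[:k])
    ci_low = float(CCF_GRID[region[0]])
    ci_high = float(CCF_GRID[region[-1]])
    clonal = ci_high >= CCF_GRID[-1]
    return CcfPosterior(CCF_GRID, probs, ccf_hat, ci_low, ci_high, bool(clonal), m)


def cohort_ccf_table(cohort: CohortDataset, normal_cn: int = 2) -> pd.DataFrame:
    """CCF calls for every damaging mutation in the cohort.

    Tumour copy number is taken from the sample-gene copy state when
    available, defaulting to 2. Benign mutations are skipped.
    """
    meta = {s.sample_id: s for s in cohort.samples}
    cn_of = {(c.sample_id, c.gene_id): c.total_cn for c in cohort.copy_states}
    rows = []
    for mut in cohort.mutations:
        if mut.consequence not in DAMAGING_MUTATION_CLASSES:
            continue
        s = meta[mut.sample_id]
        tumour_cn = max(1, cn_of.get((mut.sample_id, mut.gene_id), 2))
        post = ccf_posterior(mut.alt_reads, mut.depth, s.purity, tumour_cn,
                             normal_cn=normal_cn)
        rows.append((mut.sample_id, mut.gene_id, mut.consequence.value,
                     mut.alt_reads, mut.depth, post.ccf_hat, post.ci_low,
                     post.ci_high, post.clonal))
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "consequence",
                                       "alt", "depth", "ccf_hat", "ci_low",
                                       "ci_high", "clonal"])


def driver_clonality(ccf_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate mutation clonality to (sample, driver) level.

    A driver is clonal in a sample when it carries at least one clonal
    damaging mutation; with damaging mutations but none clonal it is
    subclonal. Sample-gene pairs without damaging mutations do not appear
    (not assessed at the mutation level).
    """
    if ccf_table.empty:
        return pd.DataFrame(columns=["sample_id", "gene_id", "clonal"])
    agg = (
        ccf_table.groupby(["sample_id", "gene_id"])["clonal"]
        .any()
        .rename("clonal")
        .reset_index()
    )
    return agg


def clonality_contrast(
    a_pos: int, a_neg: int, b_pos: int, b_neg: int,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Fisher's exact comparison of clonal proportions between two groups.

    Returns (odds ratio, p). The odds ratio uses a Haldane 0.5 correction
    when any cell is zero; the p-value comes from exact hypergeometric
    enumeration (scipy). Raises on an all-zero table.
    """
    table = np.array([[a_pos, a_neg], [b_pos, b_neg]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    _, p = fisher_exact(table, alternative=alternative)
    if (table == 0).any():
        t = table + 0.5
    else:
        t = table.astype(float)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds), float(p)
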