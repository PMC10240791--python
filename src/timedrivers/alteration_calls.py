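"""Damaging LoF/GoF alteration calling and the binary regression matrix.

A sample-gene pair carries a loss-of-function (LoF) alteration if it has a
truncating, damaging missense or damaging splicing mutation, a homozygous
deletion (copy number 0 with silenced expression), or a "double hit" — a
heterozygous loss combined with a damaging mutation. Gain-of-function (GoF)
alterations are hotspot mutations and damaging gene gains (copy number more
than twice the sample ploidy with expression significantly above the
same-cancer-type baseline, Wilcoxon rank-sum, Benjamini-Hochberg FDR).

Driver-role consistency then keeps LoF events on tumour suppressors, GoF
events on oncogenes and both on unclassified drivers, and rarely damaged
drivers are removed (fewer than five damaged samples and below 2% cohort
frequency). Retained events become a binary samples x drivers indicator
matrix, the design matrix of the ordinal screening.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from timedrivers.core_model import (
    CohortDataset,
    Consequence,
    DriverEntry,
    MutationCall,
    Role,
)

logger = logging.getLogger(__name__)


class AlterationClass(str, Enum):
    LOF = "LoF"
    GOF = "GoF"


class Source(str, Enum):
    TRUNCATING = "truncating"
    MISSENSE_DAMAGING = "missense_damaging"
    SPLICING_DAMAGING = "splicing_damaging"
    HOTSPOT = "hotspot"
    HOMOZYGOUS_LOSS = "homozygous_loss"
    HETEROZYGOUS_LOSS = "heterozygous_loss"
    DAMAGING_GAIN = "damaging_gain"
    DOUBLE_HIT = "double_hit"


SOURCE_CLASS: dict[Source, AlterationClass] = {
    Source.TRUNCATING: AlterationClass.LOF,
    Source.MISSENSE_DAMAGING: AlterationClass.LOF,
    Source.SPLICING_DAMAGING: AlterationClass.LOF,
    Source.HOTSPOT: AlterationClass.GOF,
    Source.HOMOZYGOUS_LOSS: AlterationClass.LOF,
    Source.HETEROZYGOUS_LOSS: AlterationClass.LOF,  # only via double hit
    Source.DAMAGING_GAIN: AlterationClass.GOF,
    Source.DOUBLE_HIT: AlterationClass.LOF,
}

_DAMAGING_MUTATION_SOURCES = {
    Source.TRUNCATING, Source.MISSENSE_DAMAGING,
    Source.SPLICING_DAMAGING, Source.HOTSPOT,
}


@dataclass(frozen=True)
class AlterationEvent:
    sample_id: str
    gene_id: str
    klass: AlterationClass
    source: Source


class NoRetainedDriversError(ValueError):
    """Nothing to fit: the frequency/role filters removed every driver."""


@dataclass
class AlterationMatrix:
    """Binary samples x drivers indicators with per-cell event provenance."""

    indicators: pd.DataFrame
    provenance: dict[tuple[str, str], list[AlterationEvent]] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.indicators.index)

    @property
    def drivers(self) -> list[str]:
        return list(self.indicators.columns)


# ---------------------------------------------------------------------------
# mutation channel


def mutation_events(mutations: list[MutationCall]) -> list[AlterationEvent]:
    """Map consequence classes to damaging events; benign_other yields none."""
    out = []
    for m in mutations:
        if m.consequence == Consequence.BENIGN_OTHER:
            continue
        source = Source(m.consequence.value)
        out.append(AlterationEvent(m.sample_id, m.gene_id, SOURCE_CLASS[source], source))
    return out


# ---------------------------------------------------------------------------
# copy-number channel


def call_cna_alterations(
    cohort: CohortDataset,
    fdr_threshold: float = 0.05,
    fpkm_floor: float = 1.0,
    covered_min: float = 0.25,
) -> list[AlterationEvent]:
    """Classify copy-number states into loss/gain events.

    Only states covering >= ``covered_min`` of the transcript are
    considered. Losses are classified directly from copy number and
    purity-corrected expression: homozygous loss needs copy number 0 and
    FPKM/purity below ``fpkm_floor``; heterozygous loss needs copy number
    0 or 1 and FPKM/purity above it. Candidate gains (copy number >
    2 x ploidy) are kept only when the gene's expression in gain samples is
    significantly above the same-cancer-type baseline (one-sided Wilcoxon
    rank-sum, BH-corrected within cancer type across candidate-gain genes,
    FDR < ``fdr_threshold``); genes with no baseline samples are untestable
    and dropped with a warning.
    """
    meta = {s.sample_id: s for s in cohort.samples}
    expr = cohort.expression.values
    events: list[AlterationEvent] = []
    gain_candidates: list[tuple[str, str]] = []  # (sample, gene)

    for c in cohort.copy_states:
        if c.covered_fraction < covered_min:
            continue
        s = meta[c.sample_id]
        fpkm = float(expr.at[c.gene_id, c.sample_id]) if c.gene_id in expr.index else np.nan
        if np.isnan(fpkm):
            continue
        corrected = fpkm / s.purity
        if c.total_cn > 2.0 * s.ploidy:
            gain_candidates.append((c.sample_id, c.gene_id))
        if c.total_cn == 0 and corrected < fpkm_floor:
            events.append(AlterationEvent(c.sample_id, c.gene_id,
                                          AlterationClass.LOF, Source.HOMOZYGOUS_LOSS))
        elif c.total_cn in (0, 1) and corrected > fpkm_floor:
            events.append(AlterationEvent(c.sample_id, c.gene_id,
                                          AlterationClass.LOF, Source.HETEROZYGOUS_LOSS))

    if not gain_candidates:
        return events

    cand = pd.DataFrame(gain_candidates, columns=["sample_id", "gene_id"])
    cand["cancer_type"] = cand["sample_id"].map(lambda x: meta[x].cancer_type)
    type_samples: dict[str, list[str]] = {}
    for s in cohort.samples:
        type_samples.setdefault(s.cancer_type, []).append(s.sample_id)

    # BH within each cancer type across its candidate-gain genes
    for cancer_type, grp in cand.groupby("cancer_type"):
        tested: list[tuple[str, list[str], float]] = []
        for gene, gg in grp.groupby("gene_id"):
            if gene not in expr.index:
                continue
            gain_ids = sorted(gg["sample_id"])
            baseline_ids = [sid for sid in type_samples[cancer_type] if sid not in set(gain_ids)]
            if not baseline_ids:
                warnings.warn(
                    f"{cancer_type}/{gene}: candidate gain in every sample, "
                    "no baseline; gain untestable and dropped", stacklevel=2)
                continue
            gain_expr = expr.loc[gene, gain_ids].to_numpy(float)
            base_expr = expr.loc[gene, baseline_ids].to_numpy(float)
            p = mannwhitneyu(gain_expr, base_expr, alternative="greater").pvalue
            tested.append((gene, gain_ids, float(p)))
        if not tested:
            continue
        reject, _, _, _ = multipletests([t[2] for t in tested], alpha=fdr_threshold,
                                        method="fdr_bh")[:4]
        for (gene, gain_ids, _), ok in zip(tested, reject):
            if ok:
                for sid in gain_ids:
                    events.append(AlterationEvent(sid, gene, AlterationClass.GOF,
                                                  Source.DAMAGING_GAIN))
    return events


# ---------------------------------------------------------------------------
# composition and filtering


def compose_alterations(
    mutation_evts: list[AlterationEvent],
    cna_evts: list[AlterationEvent],
) -> list[AlterationEvent]:
    """Combine channels; resolve heterozygous losses into double hits.

    A heterozygous loss alone is a single hit and yields no event; combined
    with any damaging mutation in the same sample-gene it becomes one LoF
    double-hit event. All other sources pass through unchanged.
    """
    by_pair: dict[tuple[str, str], list[AlterationEvent]] = {}
    for e in list(mutation_evts) + list(cna_evts):
        by_pair.setdefault((e.sample_id, e.gene_id), []).append(e)
    out: list[AlterationEvent] = []
    for (sid, gid), evts in by_pair.items():
        has_het_loss = any(e.source == Source.HETEROZYGOUS_LOSS for e in evts)
        has_damaging_mut = any(e.source in _DAMAGING_MUTATION_SOURCES for e in evts)
        for e in evts:
            if e.source == Source.HETEROZYGOUS_LOSS:
                continue
            out.append(e)
        if has_het_loss and has_damaging_mut:
            out.append(AlterationEvent(sid, gid, AlterationClass.LOF, Source.DOUBLE_HIT))
    return out


def apply_driver_filters(
    events: list[AlterationEvent],
    drivers: list[DriverEntry],
    cancer_type: str,
    n_samples: int,
    min_frac: float = 0.02,
    min_count: int = 5,
) -> tuple[list[str], list[AlterationEvent]]:
    """Role-consistency plus frequency filter for one cancer type.

    Tumour suppressors keep LoF events only, oncogenes GoF only,
    unclassified both. A driver is retained iff its damaged-sample count is
    >= ``min_count`` OR its damaged fraction is >= ``min_frac``.
    Returns (retained driver gene ids in catalog order, retained events).
    """
    catalog = [d for d in drivers if cancer_type in d.cancer_types]
    role_of = {d.gene_id: d.role for d in catalog}

    consistent: list[AlterationEvent] = []
    for e in events:
        role = role_of.get(e.gene_id)
        if role is None:
            continue
        if role == Role.TUMOUR_SUPPRESSOR and e.klass != AlterationClass.LOF:
            continue
        if role == Role.ONCOGENE and e.klass != AlterationClass.GOF:
            continue
        consistent.append(e)

    damaged: dict[str, set[str]] = {}
    for e in consistent:
        damaged.setdefault(e.gene_id, set()).add(e.sample_id)
    retained = [
        d.gene_id for d in catalog
        if len(damaged.get(d.gene_id, ())) >= min_count
        or (n_samples > 0 and len(damaged.get(d.gene_id, ())) / n_samples >= min_frac)
    ]
    retained_set = set(retained)
    return retained, [e for e in consistent if e.gene_id in retained_set]


def build_alteration_matrix(
    events: list[AlterationEvent],
    sample_ids: list[str],
    retained_drivers: list[str],
) -> AlterationMatrix:
    """Binary indicator matrix in catalog column order with provenance."""
    if not retained_drivers:
        raise NoRetainedDriversError("no driver passed the role/frequency filters")
    mat = pd.DataFrame(0, index=pd.Index(sample_ids, name="sample_id"),
                       columns=retained_drivers, dtype=int)
    prov: dict[tuple[str, str], list[AlterationEvent]] = {}
    for e in events:
        if e.gene_id in mat.columns and e.sample_id in mat.index:
            mat.at[e.sample_id, e.gene_id] = 1
            prov.setdefault((e.sample_id, e.gene_id), []).append(e)
    return AlterationMatrix(indicators=mat, provenance=prov)


def build_cohort_matrix(
    cohort: CohortDataset,
    fdr_threshold: float = 0.05,
    fpkm_floor: float = 1.0,
    covered_min: float = 0.25,
    min_frac: float = 0.02,
    min_count: int = 5,
) -> AlterationMatrix:
    """End-to-end alteration matrix: call, compose and filter per cancer type.

    Retention is evaluated within each cancer type, so a driver kept in one
    type contributes no indicator in a type where it failed the filters.
    """
    mut_evts = mutation_events(cohort.mutations)
    cna_evts = call_cna_alterations(cohort, fdr_threshold, fpkm_floor, covered_min)
    composed = compose_alterations(mut_evts, cna_evts)

    meta = {s.sample_id: s.cancer_type for s in cohort.samples}
    by_type: dict[str, list[AlterationEvent]] = {}
    for e in composed:
        by_type.setdefault(meta[e.sample_id], []).append(e)

    catalog_order = [d.gene_id for d in cohort.drivers]
    type_counts: dict[str, int] = {}
    for s in cohort.samples:
        type_counts[s.cancer_type] = type_counts.get(s.cancer_type, 0) + 1

    all_retained: list[str] = []
    all_events: list[AlterationEvent] = []
    for cancer_type, evts in sorted(by_type.items()):
        retained, kept = apply_driver_filters(
            evts, cohort.drivers, cancer_type, type_counts[cancer_type],
            min_frac=min_frac, min_count=min_count,
        )
        all_retained.extend(g for g in retained if g not in all_retained)
        all_events.extend(kept)
    ordered = [g for g in catalog_order if g in set(all_retained)]
    return build_alteration_matrix(all_events, [s.sample_id for s in cohort.samples], ordered)


def events_frame(events: list[AlterationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.sample_id, e.gene_id, e.klass.value, e.source.value) for e in events],
        columns=["sample_id", "gene_id", "klass", "source"],
    )
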