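"""Shared data model, TSV readers/writers and validation.

The cohort container binds five tables:

* sample metadata — cancer type, tumour purity, average ploidy;
* somatic mutation calls with a pre-annotated consequence class and read
  counts (the annotation pipeline that produces the consequence class is an
  upstream concern; the enum is trusted as input);
* gene-level total copy number with the fraction of the transcript covered
  by the underlying segment;
* a genes x samples FPKM expression matrix;
* a driver catalog (role, canonical/candidate tier, applicable cancer types).

All tables round-trip through plain tab-separated files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class Consequence(str, Enum):
    """Closed consequence vocabulary for somatic SNVs/indels."""

    TRUNCATING = "truncating"
    MISSENSE_DAMAGING = "missense_damaging"
    SPLICING_DAMAGING = "splicing_damaging"
    HOTSPOT = "hotspot"
    BENIGN_OTHER = "benign_other"


class Role(str, Enum):
    TUMOUR_SUPPRESSOR = "tumour_suppressor"
    ONCOGENE = "oncogene"
    UNCLASSIFIED = "unclassified"


class Tier(str, Enum):
    CANONICAL = "canonical"
    CANDIDATE = "candidate"


DAMAGING_MUTATION_CLASSES = frozenset(
    {
        Consequence.TRUNCATING,
        Consequence.MISSENSE_DAMAGING,
        Consequence.SPLICING_DAMAGING,
        Consequence.HOTSPOT,
    }
)


class FormatError(ValueError):
    """A file does not conform to the expected TSV dialect."""


class IntegrityError(ValueError):
    """Cross-references between cohort tables do not resolve."""


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    cancer_type: str
    purity: float
    ploidy: float
    group_labels: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class MutationCall:
    sample_id: str
    gene_id: str
    consequence: Consequence
    alt_reads: int
    depth: int


@dataclass(frozen=True)
class GeneCopyState:
    sample_id: str
    gene_id: str
    total_cn: int
    covered_fraction: float


@dataclass(frozen=True)
class DriverEntry:
    gene_id: str
    role: Role
    tier: Tier
    cancer_types: frozenset[str]


class ExpressionMatrix:
    """Non-negative FPKM matrix, genes as rows and samples as columns."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise FormatError("expression matrix has duplicate gene ids")
        if values.columns.has_duplicates:
            raise FormatError("expression matrix has duplicate sample ids")
        self._values = values.astype(float)

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def genes(self) -> list[str]:
        return list(self._values.index)

    @property
    def samples(self) -> list[str]:
        return list(self._values.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self._values.equals(other._values)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({len(self.genes)} genes x {len(self.samples)} samples)"


@dataclass
class CohortDataset:
    """Validated multi-table cohort; the unit every pipeline stage consumes."""

    samples: list[SampleMeta]
    mutations: list[MutationCall]
    copy_states: list[GeneCopyState]
    expression: ExpressionMatrix
    drivers: list[DriverEntry]

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {"sample_id": s.sample_id, "cancer_type": s.cancer_type,
                   "purity": s.purity, "ploidy": s.ploidy}
            row.update(s.group_labels)
            rows.append(row)
        return pd.DataFrame(rows).set_index("sample_id")

    def mutation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.sample_id, m.gene_id, m.consequence.value, m.alt_reads, m.depth)
             for m in self.mutations],
            columns=["sample_id", "gene_id", "consequence", "alt_reads", "depth"],
        )

    def copy_state_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.sample_id, c.gene_id, c.total_cn, c.covered_fraction)
             for c in self.copy_states],
            columns=["sample_id", "gene_id", "total_cn", "covered_fraction"],
        )

    def drivers_for(self, cancer_type: str, tier: Tier | None = None) -> list[DriverEntry]:
        out = [d for d in self.drivers if cancer_type in d.cancer_types]
        if tier is not None:
            out = [d for d in out if d.tier == tier]
        return out


@dataclass(frozen=True)
class Violation:
    """One invariant failure; violations are data, not exceptions."""

    entity: str
    field: str
    rule: str
    detail: str = ""


# ---------------------------------------------------------------------------
# readers

_REQUIRED = {
    "mutations": ["sample_id", "gene_id", "consequence", "alt_reads", "depth"],
    "gene_cn": ["sample_id", "gene_id", "total_cn", "covered_fraction"],
    "samples": ["sample_id", "cancer_type", "purity", "ploidy"],
    "drivers": ["gene_id", "role", "tier", "cancer_types"],
}


def _read_tsv(path: str | Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing} for {kind} table")
    return df


def load_cohort(
    mutation_path: str | Path,
    cna_path: str | Path,
    expression_path: str | Path,
    meta_path: str | Path,
    driver_path: str | Path,
) -> CohortDataset:
    """Read the five cohort tables and return a validated :class:`CohortDataset`.

    Unknown consequence strings are mapped to ``benign_other`` with a logged
    warning. Raises :class:`FormatError` for missing columns and
    :class:`IntegrityError` when cross-references do not resolve or a row
    violates a hard invariant (e.g. ``alt_reads > depth``).
    """
    meta_df = _read_tsv(meta_path, "samples")
    group_cols = [c for c in meta_df.columns if c not in _REQUIRED["samples"]]
    samples = [
        SampleMeta(
            sample_id=r["sample_id"],
            cancer_type=r["cancer_type"],
            purity=float(r["purity"]),
            ploidy=float(r["ploidy"]),
            group_labels={c: r[c] for c in group_cols if pd.notna(r[c])},
        )
        for r in meta_df.to_dict("records")
    ]
    known = {s.sample_id for s in samples}

    mut_df = _read_tsv(mutation_path, "mutations")
    mutations: list[MutationCall] = []
    for i, r in enumerate(mut_df.to_dict("records")):
        cons_raw = r["consequence"]
        try:
            cons = Consequence(cons_raw)
        except ValueError:
            logger.warning("row %d: unknown consequence %r mapped to benign_other", i, cons_raw)
            cons = Consequence.BENIGN_OTHER
        alt, depth = int(r["alt_reads"]), int(r["depth"])
        if alt > depth or alt < 0 or depth < 1:
            raise IntegrityError(
                f"mutations row {i} ({r['sample_id']}/{r['gene_id']}): "
                f"alt_reads={alt}, depth={depth} violates 0 <= alt_reads <= depth"
            )
        if r["sample_id"] not in known:
            raise IntegrityError(
                f"mutations row {i}: sample {r['sample_id']!r} absent from sample metadata"
            )
        mutations.append(MutationCall(r["sample_id"], r["gene_id"], cons, alt, depth))

    cn_df = _read_tsv(cna_path, "gene_cn")
    copy_states = []
    for i, r in enumerate(cn_df.to_dict("records")):
        if r["sample_id"] not in known:
            raise IntegrityError(
                f"gene_cn row {i}: sample {r['sample_id']!r} absent from sample metadata"
            )
        copy_states.append(
            GeneCopyState(r["sample_id"], r["gene_id"], int(r["total_cn"]),
                          float(r["covered_fraction"]))
        )

    expr_df = pd.read_csv(expression_path, sep="\t", index_col=0)
    expr_df.index = expr_df.index.astype(str)
    expression = ExpressionMatrix(expr_df)
    absent = known - set(expression.samples)
    if absent:
        raise IntegrityError(f"expression matrix missing sample(s) {sorted(absent)}")

    drv_df = _read_tsv(driver_path, "drivers")
    drivers = [
        DriverEntry(
            gene_id=r["gene_id"],
            role=Role(r["role"]),
            tier=Tier(r["tier"]),
            cancer_types=frozenset(t for t in str(r["cancer_types"]).split(",") if t),
        )
        for r in drv_df.to_dict("records")
    ]

    return CohortDataset(samples, mutations, copy_states, expression, drivers)


def validate_cohort(cohort: CohortDataset) -> list[Violation]:
    """Return a violation record per invariant failure; empty list iff valid.

    Pure: the same cohort always yields the same list, in a deterministic
    order (samples, mutations, copy states, expression, drivers).
    """
    out: list[Violation] = []
    seen: set[str] = set()
    for s in cohort.samples:
        if s.sample_id in seen:
            out.append(Violation(s.sample_id, "sample_id", "sample_id unique within cohort"))
        seen.add(s.sample_id)
        if not (0.0 < s.purity <= 1.0):
            out.append(Violation(s.sample_id, "purity", "purity ∈ (0,1]", f"purity={s.purity}"))
        if not s.ploidy > 0:
            out.append(Violation(s.sample_id, "ploidy", "ploidy > 0", f"ploidy={s.ploidy}"))
    known = {s.sample_id for s in cohort.samples}
    for m in cohort.mutations:
        ent = f"{m.sample_id}/{m.gene_id}"
        if not (0 <= m.alt_reads <= m.depth):
            out.append(Violation(ent, "alt_reads", "0 ≤ alt_reads ≤ depth",
                                 f"alt={m.alt_reads}, depth={m.depth}"))
        if m.depth < 1:
            out.append(Violation(ent, "depth", "depth ≥ 1"))
        if m.sample_id not in known:
            out.append(Violation(ent, "sample_id", "mutation sample exists in metadata"))
    for c in cohort.copy_states:
        ent = f"{c.sample_id}/{c.gene_id}"
        if c.total_cn < 0:
            out.append(Violation(ent, "total_cn", "total_cn ≥ 0"))
        if not (0.0 <= c.covered_fraction <= 1.0):
            out.append(Violation(ent, "covered_fraction", "covered_fraction ∈ [0,1]"))
        if c.sample_id not in known:
            out.append(Violation(ent, "sample_id", "copy state sample exists in metadata"))
    if (cohort.expression.values.to_numpy() < 0).any():
        out.append(Violation("expression", "values", "no negative FPKM entries"))
    missing = known - set(cohort.expression.samples)
    for sid in sorted(missing):
        out.append(Violation(sid, "expression", "expression covers all samples"))
    for d in cohort.drivers:
        if not d.cancer_types:
            out.append(Violation(d.gene_id, "cancer_types", "cancer_types non-empty"))
    return out


# ---------------------------------------------------------------------------
# writers (byte-stable: fixed column order, fixed float formatting)


def write_cohort_tables(cohort: CohortDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the five TSV tables; deterministic byte-for-byte output."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    meta = cohort.meta_frame().reset_index()
    paths["samples"] = out / "samples.tsv"
    meta.to_csv(paths["samples"], sep="\t", index=False, float_format="%.6g")

    paths["mutations"] = out / "mutations.tsv"
    cohort.mutation_frame().to_csv(paths["mutations"], sep="\t", index=False)

    paths["gene_cn"] = out / "gene_cn.tsv"
    cohort.copy_state_frame().to_csv(paths["gene_cn"], sep="\t", index=False,
                                     float_format="%.6g")

    paths["expression"] = out / "expression.tsv"
    expr = cohort.expression.values.copy()
    expr.index.name = "gene_id"
    expr.to_csv(paths["expression"], sep="\t", float_format="%.6g")

    paths["drivers"] = out / "drivers.tsv"
    pd.DataFrame(
        [(d.gene_id, d.role.value, d.tier.value, ",".join(sorted(d.cancer_types)))
         for d in cohort.drivers],
        columns=["gene_id", "role", "tier", "cancer_types"],
    ).to_csv(paths["drivers"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# SEG + BED preprocessing helper


def gene_copy_states_from_segments(
    seg: pd.DataFrame, genes_bed: pd.DataFrame, covered_min: float = 0.0
) -> list[GeneCopyState]:
    """Intersect SEG segments with gene models and emit per-gene copy states.

    ``seg`` uses the standard SEG dialect (``ID``, ``chrom``, ``loc.start``,
    ``loc.end`` 1-based inclusive, ``seg.mean`` carrying total copy number);
    ``genes_bed`` is BED (``chrom``, ``start``, ``end`` 0-based half-open,
    ``name``). The covered fraction of a gene is the summed overlap of
    segments sharing the gene's modal copy number divided by gene length;
    the reported ``total_cn`` is the copy number of the segment with the
    largest overlap. States with coverage below ``covered_min`` are dropped.
    """
    out: list[GeneCopyState] = []
    seg = seg.copy()
    # SEG is 1-based inclusive on disk; internal convention is 0-based half-open
    seg["start0"] = seg["loc.start"].astype(int) - 1
    seg["end0"] = seg["loc.end"].astype(int)
    seg["cn"] = seg["seg.mean"].round().astype(int)
    for (sample, chrom), seg_grp in seg.groupby(["ID", "chrom"]):
        genes = genes_bed[genes_bed["chrom"] == chrom]
        for g in genes.itertuples(index=False):
            glen = g.end - g.start
            if glen <= 0:
                continue
            ov_start = np.maximum(seg_grp["start0"].to_numpy(), g.start)
            ov_end = np.minimum(seg_grp["end0"].to_numpy(), g.end)
            ov = np.clip(ov_end - ov_start, 0, None)
            if ov.sum() == 0:
                continue
            best = int(np.argmax(ov))
            cn = int(seg_grp["cn"].to_numpy()[best])
            frac = float(ov[seg_grp["cn"].to_numpy() == cn].sum() / glen)
            if frac >= covered_min:
                out.append(GeneCopyState(str(sample), str(g.name), cn, min(frac, 1.0)))
    return out
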