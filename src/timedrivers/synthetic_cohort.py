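"""Synthetic multi-cancer-type cohorts with planted driver->TIME effects.

The generator is the ground-truth instrument of the package: every
downstream stage (alteration calling, signature scoring, ordinal screening,
clonality, burdens) can be checked against what was planted.

Generative model, per sample:

* purity ~ Uniform(0.3, 0.95); ploidy drawn from {2, 3, 4}.
* each driver of the catalog is altered independently with the base
  alteration frequency; an alteration materializes as a role-consistent
  damaging mutation (truncating for tumour suppressors, hotspot for
  oncogenes, alternating for unclassified roles).
* each mutation carries a true cancer cell fraction — 1.0 with the clonal
  fraction, otherwise Uniform(0.2, 0.8) — and read counts
  alt ~ Binomial(depth, purity * CCF * m / (purity * CNt + (1-purity) * CNn))
  with multiplicity 1 and diploid driver loci, depth ~ Poisson(depth_mean).
* the latent score of each TIME feature is the sum of the planted effects of
  the sample's altered drivers plus Gaussian noise (noise correlated at 0.3
  between the anti-tumour axes CYS/ICR/TIS, mirroring correlated but
  distinct biology).
* signature-gene expression is FPKM-like log-normal with a positive loading
  on the feature's latent axis; non-signature genes are independent
  log-normal noise. Benign background mutations (Poisson per sample) supply
  tumour mutational burden.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from timedrivers.core_model import (
    CohortDataset,
    Consequence,
    DriverEntry,
    ExpressionMatrix,
    GeneCopyState,
    MutationCall,
    Role,
    SampleMeta,
    Tier,
    write_cohort_tables,
)
from timedrivers.time_features import Feature, ScoringMethod, SignatureDef

ANTI_TUMOUR_AXES = (Feature.CYS, Feature.ICR, Feature.TIS)


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    n_types: int = 4
    samples_per_type: int | tuple[int, int] = 100
    n_canonical: int = 5
    n_candidate: int = 10
    driver_freq: float = 0.15
    planted_effects: list[tuple[str, Feature, int, float]] = field(default_factory=list)
    n_signature_genes: int = 10
    n_background_genes: int = 50
    noise_sd: float = 1.0
    anti_tumour_corr: float = 0.3
    depth_mean: int = 100
    clonal_fraction: float = 0.6
    background_mutation_rate: float = 30.0
    unclassified_every: int = 5   # every k-th driver gets an unclassified role
    seed: int = 0

    def validate(self) -> None:
        for name, frac in [("driver_freq", self.driver_freq),
                           ("clonal_fraction", self.clonal_fraction)]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must lie in [0,1]")
        for name, count in [("n_types", self.n_types),
                            ("n_signature_genes", self.n_signature_genes)]:
            if count < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.depth_mean < 1:
            raise ConfigError("depth_mean must be >= 1")
        for gene, feature, sign, size in self.planted_effects:
            if sign not in (-1, 1):
                raise ConfigError(f"effect sign for {gene} must be -1 or +1")
            if size < 0:
                raise ConfigError(f"effect size for {gene} must be non-negative")


@dataclass
class GroundTruth:
    planted_effects: pd.DataFrame     # gene, feature, sign, size
    true_ccf: pd.DataFrame            # sample_id, gene_id, ccf
    latent_scores: pd.DataFrame       # samples x features
    signatures: dict[Feature, list[str]]
    alteration_status: pd.DataFrame   # samples x drivers binary


def _driver_catalog(cfg: SimConfig, cancer_types: list[str]) -> list[DriverEntry]:
    drivers = []
    all_types = frozenset(cancer_types)
    for tier, n, prefix in [(Tier.CANONICAL, cfg.n_canonical, "DRV_CANON"),
                            (Tier.CANDIDATE, cfg.n_candidate, "DRV_CAND")]:
        for i in range(n):
            if cfg.unclassified_every and (i + 1) % cfg.unclassified_every == 0:
                role = Role.UNCLASSIFIED
            else:
                role = Role.TUMOUR_SUPPRESSOR if i % 2 == 0 else Role.ONCOGENE
            drivers.append(DriverEntry(f"{prefix}_{i + 1:03d}", role, tier, all_types))
    return drivers


def simulate_cohort(cfg: SimConfig) -> tuple[CohortDataset, GroundTruth]:
    """Draw one cohort and its ground truth; deterministic given cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    cancer_types = [f"CT{i + 1:02d}" for i in range(cfg.n_types)]
    drivers = _driver_catalog(cfg, cancer_types)
    driver_ids = [d.gene_id for d in drivers]
    role_of = {d.gene_id: d.role for d in drivers}
    for gene, _, _, _ in cfg.planted_effects:
        if gene not in role_of:
            raise ConfigError(f"planted gene {gene!r} absent from the driver catalog")

    # samples -----------------------------------------------------------
    samples: list[SampleMeta] = []
    for t in cancer_types:
        if isinstance(cfg.samples_per_type, tuple):
            lo, hi = cfg.samples_per_type
            n = int(rng.integers(lo, hi + 1))
        else:
            n = int(cfg.samples_per_type)
        for i in range(n):
            samples.append(SampleMeta(
                sample_id=f"{t}_S{i + 1:04d}",
                cancer_type=t,
                purity=float(np.round(rng.uniform(0.3, 0.95), 4)),
                ploidy=float(rng.choice([2, 3, 4], p=[0.6, 0.25, 0.15])),
            ))
    sample_ids = [s.sample_id for s in samples]
    n_samples = len(samples)

    # driver alterations ------------------------------------------------
    status = pd.DataFrame(
        (rng.random((n_samples, len(driver_ids))) < cfg.driver_freq).astype(int),
        index=pd.Index(sample_ids, name="sample_id"), columns=driver_ids,
    )

    # mutations with read counts ---------------------------------------
    mutations: list[MutationCall] = []
    ccf_rows = []
    purity_of = {s.sample_id: s.purity for s in samples}
    unclassified_flip = 0
    for sid in sample_ids:
        for gid in driver_ids:
            if not status.at[sid, gid]:
                continue
            role = role_of[gid]
            if role == Role.TUMOUR_SUPPRESSOR:
                cons = Consequence.TRUNCATING
            elif role == Role.ONCOGENE:
                cons = Consequence.HOTSPOT
            else:
                cons = (Consequence.TRUNCATING if unclassified_flip % 2 == 0
                        else Consequence.HOTSPOT)
                unclassified_flip += 1
            ccf = 1.0 if rng.random() < cfg.clonal_fraction else float(rng.uniform(0.2, 0.8))
            rho = purity_of[sid]
            vaf = rho * ccf * 1 / (rho * 2 + (1 - rho) * 2)  # diploid locus, m=1
            depth = max(int(rng.poisson(cfg.depth_mean)), 10)
            alt = int(rng.binomial(depth, vaf))
            mutations.append(MutationCall(sid, gid, cons, alt, depth))
            ccf_rows.append((sid, gid, ccf))

    # benign background mutations for TMB -------------------------------
    bg_genes = [f"BG_{i + 1:04d}" for i in range(cfg.n_background_genes)]
    for sid in sample_ids:
        k = int(rng.poisson(cfg.background_mutation_rate))
        genes = rng.choice(bg_genes, size=k, replace=True)
        for gid in genes:
            depth = max(int(rng.poisson(cfg.depth_mean)), 10)
            rho = purity_of[sid]
            alt = int(rng.binomial(depth, rho * 0.5 / 2 + 0.05))
            mutations.append(MutationCall(sid, str(gid), Consequence.BENIGN_OTHER,
                                          alt, depth))

    # copy states: driver loci diploid, fully covered --------------------
    copy_states = [GeneCopyState(sid, gid, 2, 1.0)
                   for sid in sample_ids for gid in driver_ids]

    # latent TIME axes ---------------------------------------------------
    features = list(Feature)
    corr = np.eye(len(features))
    for i, fi in enumerate(features):
        for j, fj in enumerate(features):
            if i != j and fi in ANTI_TUMOUR_AXES and fj in ANTI_TUMOUR_AXES:
                corr[i, j] = cfg.anti_tumour_corr
    chol = np.linalg.cholesky(corr)
    noise = rng.standard_normal((n_samples, len(features))) @ chol.T * cfg.noise_sd
    latent = pd.DataFrame(noise, index=sample_ids,
                          columns=[f.value for f in features])
    for gene, feature, sign, size in cfg.planted_effects:
        latent[feature.value] += status[gene].to_numpy() * sign * size

    # expression ---------------------------------------------------------
    signatures: dict[Feature, list[str]] = {
        f: [f"SIG_{f.value}_{i + 1:03d}" for i in range(cfg.n_signature_genes)]
        for f in features
    }
    expr_blocks = []
    gene_order = []
    for f in features:
        loadings = rng.uniform(0.5, 1.5, size=cfg.n_signature_genes)
        base = rng.normal(1.5, 0.3, size=cfg.n_signature_genes)
        eps = rng.normal(0.0, 0.3, size=(cfg.n_signature_genes, n_samples))
        logexp = base[:, None] + np.outer(loadings, latent[f.value].to_numpy()) + eps
        expr_blocks.append(np.exp(logexp))
        gene_order.extend(signatures[f])
    noise_genes = [f"NSG_{i + 1:04d}" for i in range(cfg.n_background_genes)]
    expr_blocks.append(np.exp(rng.normal(1.5, 1.0,
                                         size=(cfg.n_background_genes, n_samples))))
    gene_order.extend(noise_genes)
    expression = ExpressionMatrix(pd.DataFrame(
        np.round(np.vstack(expr_blocks), 6), index=gene_order, columns=sample_ids,
    ))

    cohort = CohortDataset(samples, mutations, copy_states, expression, drivers)
    truth = GroundTruth(
        planted_effects=pd.DataFrame(
            [(g, f.value, s, z) for g, f, s, z in cfg.planted_effects],
            columns=["gene", "feature", "sign", "size"],
        ),
        true_ccf=pd.DataFrame(ccf_rows, columns=["sample_id", "gene_id", "ccf"]),
        latent_scores=latent,
        signatures=signatures,
        alteration_status=status,
    )
    return cohort, truth


def signature_defs_from_truth(
    truth: GroundTruth, quartile_only: bool = False
) -> list[SignatureDef]:
    """Signature definitions over the simulator's gene lists.

    ``quartile_only`` scores every feature by mean-log2 + per-type quartiles
    instead of the clustered CYS/ICR defaults — convenient when small
    per-type sample sizes would make globally clustered levels degenerate
    within a type.
    """
    defs = []
    for f, genes in truth.signatures.items():
        method = ScoringMethod.MEAN_LOG2 if quartile_only else None
        defs.append(SignatureDef(feature=f, genes=genes, method=method))
    return defs


def write_cohort(cohort: CohortDataset, truth: GroundTruth,
                 out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort TSVs plus ground-truth tables; byte-stable."""
    out = Path(out_dir)
    paths = write_cohort_tables(cohort, out)
    paths["ground_truth"] = out / "ground_truth.tsv"
    truth.planted_effects.to_csv(paths["ground_truth"], sep="\t", index=False,
                                 float_format="%.6g")
    paths["true_ccf"] = out / "true_ccf.tsv"
    truth.true_ccf.to_csv(paths["true_ccf"], sep="\t", index=False,
                          float_format="%.6g")
    paths["latent_scores"] = out / "latent_scores.tsv"
    latent = truth.latent_scores.copy()
    latent.index.name = "sample_id"
    latent.to_csv(paths["latent_scores"], sep="\t", float_format="%.6g")
    sig_dir = out / "signatures"
    sig_dir.mkdir(exist_ok=True)
    for f, genes in truth.signatures.items():
        pd.DataFrame({"gene_id": genes}).to_csv(sig_dir / f"{f.value}.tsv",
                                                sep="\t", index=False)
    paths["signatures"] = sig_dir
    return paths
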