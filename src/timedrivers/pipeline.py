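"""End-to-end orchestration with a reproducibility manifest.

Runs the stages in order — simulate (or load) a cohort, call alterations,
score TIME features, screen driver-TIME interactions, call clonality, and
compute burdens — writing each stage's TSV output plus a JSON manifest of
config hash, seed, package version, per-file digests and the per-stratum
fit log. Identical config and inputs reproduce identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

import timedrivers
from timedrivers.alteration_calls import build_cohort_matrix, events_frame
from timedrivers.clonality import cohort_ccf_table, driver_clonality
from timedrivers.core_model import CohortDataset, load_cohort
from timedrivers.burden_response import compute_burdens, compute_tmb
from timedrivers.ordinal_lasso import discover_time_drivers, records_frame
from timedrivers.synthetic_cohort import (
    SimConfig,
    signature_defs_from_truth,
    simulate_cohort,
    write_cohort,
)
from timedrivers.time_features import Feature, compute_time_levels

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed (< 2**31) from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    version: str
    files: dict[str, str] = field(default_factory=dict)
    fit_log: list[dict[str, Any]] = field(default_factory=list)
    n_fits: int = 0

    def write(self, path: Path) -> None:
        path.write_text(json.dumps({
            "seed": self.seed, "config_hash": self.config_hash,
            "version": self.version, "files": self.files,
            "n_fits": self.n_fits, "fit_log": self.fit_log,
        }, indent=1, sort_keys=True))


def run_all(config: dict[str, Any], out_dir: str | Path) -> RunManifest:
    """Execute the full pipeline per the config mapping; return the manifest.

    ``config["simulate"]`` holds :class:`SimConfig` keyword arguments (a
    ``cohort_dir`` key loads an on-disk cohort instead); ``config["seed"]``
    is the global seed fanned out to stages by stable hashing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(seed=seed, config_hash=config_hash,
                           version=timedrivers.__version__)

    truth = None
    if "cohort_dir" in config:
        d = Path(config["cohort_dir"])
        cohort = load_cohort(d / "mutations.tsv", d / "gene_cn.tsv",
                             d / "expression.tsv", d / "samples.tsv",
                             d / "drivers.tsv")
    else:
        sim_kwargs = dict(config.get("simulate", {}))
        sim_kwargs.setdefault("seed", stage_seed(seed, "simulate"))
        if "planted_effects" in sim_kwargs:
            sim_kwargs["planted_effects"] = [
                (g, Feature(f), int(s), float(z))
                for g, f, s, z in sim_kwargs["planted_effects"]
            ]
        cohort, truth = simulate_cohort(SimConfig(**sim_kwargs))
        paths = write_cohort(cohort, truth, out / "cohort")
        for k, p in paths.items():
            if p.is_file():
                manifest.files[f"cohort/{k}"] = _digest(p)

    matrix = build_cohort_matrix(cohort, **config.get("alterations", {}))
    alt_path = out / "alterations.tsv"
    ev = [e for evs in matrix.provenance.values() for e in evs]
    events_frame(ev).to_csv(alt_path, sep="\t", index=False)
    manifest.files["alterations"] = _digest(alt_path)

    if truth is not None:
        sig_defs = signature_defs_from_truth(
            truth, quartile_only=bool(config.get("quartile_only", False)))
    else:
        from timedrivers.time_features import read_signature_dir
        sig_defs = read_signature_dir(config["signature_dir"])
    levels = compute_time_levels(cohort, sig_defs, seed=stage_seed(seed, "cluster"))
    lv_path = out / "time_levels.tsv"
    levels.to_long_frame().to_csv(lv_path, sep="\t", index=False, float_format="%.6g")
    manifest.files["time_levels"] = _digest(lv_path)

    records, logs = discover_time_drivers(cohort, matrix, levels,
                                          **config.get("discover", {}))
    rec_path = out / "time_drivers.tsv"
    records_frame(records).to_csv(rec_path, sep="\t", index=False, float_format="%.6g")
    manifest.files["time_drivers"] = _digest(rec_path)
    manifest.n_fits = sum(l.fitted for l in logs)
    manifest.fit_log = [
        {"cancer_type": l.cancer_type, "feature": l.feature.value,
         "tier": l.tier.value, "n": l.n_samples, "fitted": l.fitted,
         "reason": l.reason, "lambda": None if l.selected_lambda != l.selected_lambda
         else l.selected_lambda, "df": None if l.df != l.df else l.df}
        for l in logs
    ]

    ccf = cohort_ccf_table(cohort)
    ccf_path = out / "ccf.tsv"
    ccf.to_csv(ccf_path, sep="\t", index=False, float_format="%.6g")
    manifest.files["ccf"] = _digest(ccf_path)
    driver_clonality(ccf).to_csv(out / "driver_clonality.tsv", sep="\t", index=False)

    _, median_tmb = compute_tmb(cohort)
    burdens = compute_burdens(records, cohort.drivers)
    burden = burdens.join(median_tmb, how="outer").fillna(0)
    burden_path = out / "burden.tsv"
    burden.to_csv(burden_path, sep="\t", float_format="%.6g")
    manifest.files["burden"] = _digest(burden_path)

    manifest.write(out / "manifest.json")
    return manifest
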