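"""Validated pipeline configuration and end-to-end experiment orchestration.

``run_experiment`` reproduces the experiment shape on synthetic data:
generate a cohort, split it 30/70 into development and validation by
encounter, calibrate the likelihood table and the SLT threshold alpha on the
development split, then run all four alert variants on the validation split
and report metrics per variant. Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .alerts import AlertConfig, SurrogateScorer, run_cohort, slt_decision
from .cohort import CohortSpec, generate_cohort
from .ddx import (
    BACTERIAL_SUSPICION,
    CalibrationRecord,
    SearchSpec,
    calibrate,
    load_default_tables,
    sepsis_likelihood,
)
from .evaluation import ClinicalResponsePolicy, MetricsReport, cohort_report
from .model import Encounter
from .phenotype import PhenotypeConfig
from .retrieval import MockLLMBackend, RetrievalConfig, extract_all

logger = logging.getLogger("edsepsis")

VARIANTS = ("composer_only", "ddx", "slt", "baseline")


class PipelineConfig(BaseModel):
    """Composition of all stage configurations, validated at load time."""

    model_config = ConfigDict(extra="forbid")

    cohort: CohortSpec = Field(default_factory=lambda: CohortSpec(n_encounters=2000))
    phenotype: PhenotypeConfig = Field(default_factory=PhenotypeConfig)
    retrieval: RetrievalConfig = Field(default_factory=RetrievalConfig)
    alert: AlertConfig = Field(default_factory=AlertConfig)
    policy: ClinicalResponsePolicy = Field(default_factory=ClinicalResponsePolicy)
    calibration_budget: int = 100
    dev_fraction: float = 0.3
    log_level: str = "INFO"


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; omitted fields take the defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    return PipelineConfig.model_validate(raw)


def split_cohort(
    encounters: Sequence[Encounter], dev_fraction: float, seed: int
) -> tuple[list[Encounter], list[Encounter]]:
    """Seeded encounter-level development/validation split."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(encounters))
    n_dev = int(round(dev_fraction * len(encounters)))
    dev_idx = set(order[:n_dev].tolist())
    dev = [e for i, e in enumerate(encounters) if i in dev_idx]
    val = [e for i, e in enumerate(encounters) if i not in dev_idx]
    return dev, val


def extraction_records(
    encounters: Sequence[Encounter],
    retrieval_config: RetrievalConfig,
    backend,
    catalog,
) -> list[CalibrationRecord]:
    """Run the extractor over each encounter's notes and pair with labels."""
    records = []
    for e in encounters:
        if e.truth is None:
            raise ValueError(f"encounter {e.encounter_id} is unlabeled")
        present, _ = extract_all(
            list(catalog),
            e.notes,
            retrieval_config,
            backend,
            catalog=catalog,
            encounter_id=e.encounter_id,
        )
        records.append(
            CalibrationRecord(
                present=frozenset(present),
                septic=e.truth.septic,
                diagnosis=e.truth.diagnosis,
            )
        )
    return records


def calibrate_alpha(records: Sequence[CalibrationRecord], table) -> float:
    """Pick the SLT threshold maximizing development F1 of the SLT rule."""
    liks = sorted({round(sepsis_likelihood(r.present, table), 12) for r in records})
    candidates = [0.0] + [l - 1e-9 for l in liks]
    best_alpha, best_f1 = 0.0, -1.0
    for alpha in candidates:
        tp = fp = fn = 0
        for r in records:
            lik = sepsis_likelihood(r.present, table)
            fire = lik > alpha and BACTERIAL_SUSPICION in r.present
            if fire and r.septic:
                tp += 1
            elif fire:
                fp += 1
            elif r.septic:
                fn += 1
        if tp == 0:
            f1 = 0.0
        else:
            sens = tp / (tp + fn)
            ppv = tp / (tp + fp)
            f1 = 2 * sens * ppv / (sens + ppv)
        if f1 > best_f1:
            best_alpha, best_f1 = alpha, f1
    return best_alpha


def run_experiment(
    config: PipelineConfig, audit_dir: Optional[str | Path] = None
) -> dict[str, MetricsReport]:
    """Synth -> split -> calibrate -> run all variants -> metrics per variant."""
    catalog, table = load_default_tables()
    backend = MockLLMBackend()
    scorer = SurrogateScorer()

    encounters = generate_cohort(config.cohort, catalog, table)
    dev, val = split_cohort(encounters, config.dev_fraction, config.cohort.seed)
    logger.info(json.dumps({"event": "split", "dev": len(dev), "val": len(val)}))

    dev_records = extraction_records(dev, config.retrieval, backend, catalog)
    cal_table = calibrate(
        dev_records,
        table,
        SearchSpec(budget=config.calibration_budget, seed=config.cohort.seed),
    )
    alpha = calibrate_alpha(dev_records, cal_table)
    logger.info(json.dumps({"event": "calibrated", "alpha": alpha}))

    reports: dict[str, MetricsReport] = {}
    for variant in VARIANTS:
        alert_config = config.alert.model_copy(
            update={"variant": variant, "alpha": alpha}
        )
        alarms = run_cohort(
            val, scorer, backend, alert_config, config.retrieval, catalog, cal_table
        )
        reports[variant] = cohort_report(val, alarms, alert_config, config.policy)
        if audit_dir is not None:
            path = Path(audit_dir) / f"alarms_{variant}.jsonl"
            path.parent.mkdir(parents=True, exist_ok=True)
            with open(path, "w") as fh:
                for enc_alarms in alarms.values():
                    for a in enc_alarms:
                        fh.write(json.dumps(a.__dict__, default=list) + "\n")
        logger.info(
            json.dumps({"event": "variant_report", "variant": variant,
                        **reports[variant].rounded()})
        )
    return reports
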