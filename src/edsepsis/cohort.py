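"""Synthetic ED cohort generator.

Generates encounters with the statistical/temporal structure the alerting
pipeline assumes: hourly vitals/labs coverage, order events that satisfy or
violate the suspicion-of-infection timing windows, SOFA trajectories that do
or do not qualify under the Sepsis-3 rule, and notes carrying planted
canonical phrases for the generator's true present-symptom set.

Septic onset delay is log-normal with median ``onset_delay_median_hr``
(default 3.2 h), truncated below so onset falls after the prediction start.
Non-septic encounters receive a sepsis-mimic truth diagnosis with
probability ``mimic_fraction``; mimic symptoms are sampled per-sign from the
mimic's likelihood row, septic symptoms from the severe-sepsis row.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .ddx import (
    SEVERE_SEPSIS,
    LikelihoodTable,
    SymptomCatalog,
    load_default_tables,
)
from .model import Encounter, NoteEvent, OrderEvent, SuspicionEvent, TruthRecord
from .retrieval import canonical_phrase

# sigma of the log-normal onset delay; yields an IQR ratio of roughly
# exp(2 * 0.675 * sigma) ~ 4.4, comparable to a 1.6-7.5 h IQR at median 3.2 h
_ONSET_SIGMA = 1.1
_MIN_ONSET = 2.5
_MAX_ONSET = 40.0

_FILLERS = (
    "Patient arrived to the emergency department and was triaged promptly.",
    "Past medical history reviewed with the patient and family at bedside.",
    "Review of systems otherwise negative except as documented above.",
    "Plan discussed with the care team; will continue to monitor closely.",
    "Vital signs obtained and repeated per department protocol.",
)


class CohortSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_encounters: int
    septic_fraction: float = 0.166
    onset_delay_median_hr: float = 3.2
    note_symptom_noise: float = 0.0
    mimic_fraction: float = 0.8
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if self.n_encounters < 1:
            raise ValueError("n_encounters must be >= 1")
        for f in ("septic_fraction", "note_symptom_noise", "mimic_fraction"):
            if not (0.0 <= getattr(self, f) <= 1.0):
                raise ValueError(f"{f} must be a probability in [0, 1]")
        if self.onset_delay_median_hr <= 0:
            raise ValueError("onset_delay_median_hr must be positive")
        return self


def plant_symptom_phrases(
    truth_symptoms: set[str],
    noise: float,
    seed: int,
    catalog: Optional[SymptomCatalog] = None,
) -> str:
    """Note text embedding each true symptom's canonical phrase.

    Each true symptom's phrase appears with probability ``1 - noise``; each
    other catalog symptom's phrase appears as a decoy with probability
    ``noise``. Filler sentences never contain catalog phrases.
    """
    if catalog is None:
        catalog, _ = load_default_tables()
    catalog.validate(truth_symptoms)
    rng = np.random.default_rng(seed)
    sentences = [_FILLERS[int(rng.integers(len(_FILLERS)))]]
    for symptom in catalog:
        truly_present = symptom in truth_symptoms
        include = rng.random() < (1.0 - noise if truly_present else noise)
        if include:
            sentences.append(f"Exam notable for {canonical_phrase(symptom)}.")
    sentences.append(_FILLERS[int(rng.integers(len(_FILLERS)))])
    return " ".join(sentences)


def _sample_symptoms(
    rng: np.random.Generator, table: LikelihoodTable, disease: str
) -> set[str]:
    row = table.lik[disease]
    return {s for s in sorted(row) if rng.random() < row[s]}


def _sofa_series(
    rng: np.random.Generator,
    discharge: float,
    onset: Optional[float],
    base: int,
) -> list[tuple[float, int]]:
    hours = [float(h) for h in range(0, int(math.floor(discharge)) + 1)]
    if onset is not None and onset not in hours:
        hours.append(onset)
    hours.sort()
    series = []
    for h in hours:
        if onset is not None and h >= onset:
            v = base + 2 + int(rng.integers(0, 3))
        else:
            v = base
        series.append((h, v))
    return series


def _generate_septic(
    rng: np.random.Generator,
    spec: CohortSpec,
    table: LikelihoodTable,
) -> dict:
    mu = math.log(spec.onset_delay_median_hr)
    onset = float(rng.lognormal(mu, _ONSET_SIGMA))
    onset = min(max(onset, _MIN_ONSET), _MAX_ONSET)
    onset = round(onset, 2)
    culture = round(max(0.25, onset - 1.0), 2)
    abx_start = round(onset + 0.5, 2)
    abx_end = round(abx_start + 100.0 + float(rng.uniform(0, 24)), 2)
    stay_end = onset + float(rng.lognormal(math.log(18.0), 0.5))
    discharge = round(max(stay_end, abx_end) + 1.0, 2)
    orders = [
        OrderEvent(kind="blood_culture", hour=culture),
        OrderEvent(kind="iv_antibiotic_start", hour=abx_start),
        OrderEvent(kind="iv_antibiotic_end", hour=abx_end),
    ]
    symptoms = _sample_symptoms(rng, table, SEVERE_SEPSIS)
    truth = TruthRecord(
        septic=True,
        onset_hour=onset,
        suspicion=SuspicionEvent(
            suspicion_hour=culture, culture_hour=culture, abx_start_hour=abx_start
        ),
        symptoms=sorted(symptoms),
        diagnosis=SEVERE_SEPSIS,
    )
    severity = float(rng.normal(1.0, 0.9))
    return dict(
        orders=orders, truth=truth, discharge=discharge, onset=onset,
        severity=severity, sofa_base=int(rng.integers(0, 2)),
    )


def _generate_non_septic(
    rng: np.random.Generator,
    spec: CohortSpec,
    table: LikelihoodTable,
) -> dict:
    discharge = round(max(6.0, float(rng.lognormal(math.log(11.0), 0.6))), 2)
    mimics = [d for d in table.diseases if d != SEVERE_SEPSIS]
    orders: list[OrderEvent] = []
    if rng.random() < spec.mimic_fraction:
        diagnosis = mimics[int(rng.integers(len(mimics)))]
        symptoms = _sample_symptoms(rng, table, diagnosis)
        severity = float(rng.normal(0.0, 0.7))
    else:
        diagnosis = None
        symptoms = set()
        severity = float(rng.normal(-2.0, 0.8))
    # a minority get a culture + short (non-qualifying) antibiotic course,
    # exercising the suspected-infection subgroup and eligibility cutoffs
    if diagnosis is not None and rng.random() < 0.2 and discharge > 8.0:
        culture = round(float(rng.uniform(1.0, 3.0)), 2)
        abx_start = round(culture + float(rng.uniform(2.0, 5.0)), 2)
        abx_end = round(min(abx_start + float(rng.uniform(24.0, 72.0)), discharge), 2)
        if abx_end > abx_start:
            orders = [
                OrderEvent(kind="blood_culture", hour=culture),
                OrderEvent(kind="iv_antibiotic_start", hour=abx_start),
                OrderEvent(kind="iv_antibiotic_end", hour=abx_end),
            ]
    truth = TruthRecord(septic=False, symptoms=sorted(symptoms), diagnosis=diagnosis)
    return dict(
        orders=orders, truth=truth, discharge=discharge, onset=None,
        severity=severity, sofa_base=int(rng.integers(0, 3)),
    )


def generate_cohort(
    spec: CohortSpec,
    catalog: Optional[SymptomCatalog] = None,
    table: Optional[LikelihoodTable] = None,
) -> list[Encounter]:
    """Generate ``spec.n_encounters`` synthetic encounters, deterministically."""
    if catalog is None or table is None:
        default_catalog, default_table = load_default_tables()
        catalog = catalog or default_catalog
        table = table or default_table
    rng = np.random.default_rng(spec.seed)
    encounters = []
    for i in range(spec.n_encounters):
        septic = bool(rng.random() < spec.septic_fraction)
        parts = (
            _generate_septic(rng, spec, table)
            if septic
            else _generate_non_septic(rng, spec, table)
        )
        discharge = parts["discharge"]
        vitals = [round(h + 0.2, 2) for h in range(int(discharge))]
        labs = [round(h + 0.8, 2) for h in range(0, int(discharge), 4)]
        note_seed = int(rng.integers(2**31))
        truth: TruthRecord = parts["truth"]
        notes = [
            NoteEvent(
                note_id="note-ed",
                note_type="ED provider note",
                hour=0.5,
                text=plant_symptom_phrases(
                    set(truth.symptoms or []), spec.note_symptom_noise, note_seed, catalog
                ),
            ),
            NoteEvent(
                note_id="note-hp",
                note_type="History and Physical note",
                hour=1.0,
                text=" ".join(_FILLERS[:3]),
                complete=bool(rng.random() < 0.9),
            ),
        ]
        encounters.append(
            Encounter(
                encounter_id=f"enc{i:05d}",
                vitals_times=vitals,
                labs_times=labs,
                sofa_series=_sofa_series(
                    rng, discharge, parts["onset"], parts["sofa_base"]
                ),
                orders=parts["orders"],
                notes=notes,
                discharge_hour=discharge,
                severity=parts["severity"],
                truth=truth,
            )
        )
    return encounters


# --------------------------------------------------------------------------
# Serialization

SCHEMA_VERSION = 1


def write_cohort_jsonl(encounters: Sequence[Encounter], path: str | Path) -> None:
    with open(path, "w") as fh:
        for enc in encounters:
            record = {"schema_version": SCHEMA_VERSION, **enc.model_dump()}
            fh.write(json.dumps(record, sort_keys=True) + "\n")


def read_cohort_jsonl(path: str | Path) -> list[Encounter]:
    encounters = []
    with open(path) as fh:
        for line in fh:
            record = json.loads(line)
            record.pop("schema_version", None)
            encounters.append(Encounter.model_validate(record))
    return encounters


def cohort_to_frames(encounters: Sequence[Encounter]):
    """Flattened event tables (encounters, events) as pandas DataFrames."""
    import pandas as pd

    enc_rows, event_rows = [], []
    for e in encounters:
        t = e.truth
        enc_rows.append(
            {
                "encounter_id": e.encounter_id,
                "discharge_hour": e.discharge_hour,
                "severity": e.severity,
                "septic": t.septic if t else None,
                "onset_hour": t.onset_hour if t else None,
                "diagnosis": t.diagnosis if t else None,
            }
        )
        for v in e.vitals_times:
            event_rows.append({"encounter_id": e.encounter_id, "kind": "vital", "hour": v})
        for l in e.labs_times:
            event_rows.append({"encounter_id": e.encounter_id, "kind": "lab", "hour": l})
        for o in e.orders:
            event_rows.append({"encounter_id": e.encounter_id, "kind": o.kind, "hour": o.hour})
        for h, s in e.sofa_series:
            event_rows.append(
                {"encounter_id": e.encounter_id, "kind": "sofa", "hour": h, "value": s}
            )
    return pd.DataFrame(enc_rows), pd.DataFrame(event_rows)
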