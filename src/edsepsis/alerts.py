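"""Hourly alerting: eligibility, risk-score gating, alert variants, silencing.

Gating convention (boundaries inclusive as noted): ``score >= theta1`` fires
directly; ``theta2 <= score < theta1`` enters the LLM zone where note-derived
evidence adjudicates; below ``theta2`` no action. After any fired alarm,
firing (not scoring) is suppressed for ``silencing_hours``; the silencing
clock is shared across the direct and LLM-gated pathways.

The monitoring loop covers integer hours in the closed-open interval
``[prediction_start, monitoring_end)`` where monitoring ends at the first
sepsis onset or discharge, whichever is earlier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Protocol, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from . import ddx as ddx_mod
from . import retrieval as retrieval_mod
from .ddx import BACTERIAL_SUSPICION, SEVERE_SEPSIS, LikelihoodTable, SymptomCatalog
from .model import NOTE_TYPES, Encounter
from .retrieval import ExtractorBackend, HashingEmbedder, RetrievalConfig

Zone = Literal["direct", "llm_gated"]
GateAction = Literal["direct_fire", "llm_zone", "no_action"]
Variant = Literal["ddx", "slt", "baseline", "composer_only"]


class ConfigError(ValueError):
    pass


class AlertConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    theta1: float = 0.75
    theta2: float = 0.5
    alpha: Optional[float] = None
    silencing_hours: float = 6.0
    truth_window_hours: float = 48.0
    prediction_start: float = 2.0
    required_note_types: tuple[str, ...] = NOTE_TYPES
    variant: Variant = "ddx"
    composer_only_threshold: float = 0.6

    @model_validator(mode="after")
    def _check(self) -> "AlertConfig":
        if not (0.0 <= self.theta2 < self.theta1 <= 1.0):
            raise ValueError("thresholds must satisfy 0 <= theta2 < theta1 <= 1")
        if self.silencing_hours <= 0 or self.truth_window_hours <= 0:
            raise ValueError("silencing and truth windows must be positive")
        return self


class RiskScorer(Protocol):
    def score(self, encounter: Encounter, hour: float) -> float:
        ...


class SurrogateScorer:
    """Logistic risk score over the generator's latent severity feature.

    Stands in for the (out-of-scope) structured-data risk model; by
    construction a neutral severity of 0 maps to 0.5 and the score is
    monotone in severity, so synthetic cohorts straddle both thresholds.
    """

    def __init__(self, scale: float = 1.0, offset: float = 0.0):
        self.scale = scale
        self.offset = offset

    def score(self, encounter: Encounter, hour: float) -> float:
        z = self.scale * (encounter.severity - self.offset)
        return 1.0 / (1.0 + math.exp(-z))


class ConstantScorer:
    def __init__(self, value: float):
        self.value = value

    def score(self, encounter: Encounter, hour: float) -> float:
        return self.value


@dataclass
class AlarmRecord:
    """One gate evaluation: either a direct fire or an LLM-zone decision."""

    encounter_id: str
    hour: float
    zone: Zone
    fired: bool
    score: float
    ddx_topk: Optional[list[str]] = None
    bacterial_suspicion: Optional[bool] = None
    justifications: Optional[dict[str, str]] = None


def eligible(encounter: Encounter, hour: float, config: AlertConfig) -> bool:
    """Prediction eligibility at ``hour``.

    Requires at least one vital and one lab in the half-open 24 h lookback
    ``(hour - 24, hour]``, no antibiotic started at or before ``hour``, and
    at least one note of a required type available by ``hour``.
    """
    if hour < config.prediction_start:
        return False
    lo = hour - 24.0
    if not any(lo < t <= hour for t in encounter.vitals_times):
        return False
    if not any(lo < t <= hour for t in encounter.labs_times):
        return False
    for o in encounter.orders:
        if o.kind == "iv_antibiotic_start" and o.hour <= hour:
            return False
    return any(
        n.hour <= hour and n.note_type in config.required_note_types
        for n in encounter.notes
    )


def gate(score: float, config: AlertConfig) -> GateAction:
    if not (0.0 <= score <= 1.0):
        raise ValueError("risk score must lie in [0, 1]")
    if score >= config.theta1:
        return "direct_fire"
    if score >= config.theta2:
        return "llm_zone"
    return "no_action"


def ddx_decision(topk: Sequence[str], bacterial_suspicion: bool) -> bool:
    """Fire iff severe sepsis is in the top-5 and bacterial suspicion holds."""
    return SEVERE_SEPSIS in topk and bacterial_suspicion


def slt_decision(
    sepsis_likelihood: float, bacterial_suspicion: bool, config: AlertConfig
) -> bool:
    """Fire iff the sepsis likelihood strictly exceeds alpha and suspicion holds."""
    if config.alpha is None:
        raise ConfigError("slt variant requires a calibrated alpha")
    return sepsis_likelihood > config.alpha and bacterial_suspicion


def baseline_decision(
    notes,
    backend: ExtractorBackend,
    config: AlertConfig,
    retrieval_config: RetrievalConfig,
    encounter_id: str = "",
) -> bool:
    """Fire iff the direct sepsis query's majority answer is yes."""
    result = retrieval_mod.extract_sepsis_direct(
        notes, retrieval_config, backend, encounter_id=encounter_id
    )
    return result.present


def monitoring_end(encounter: Encounter) -> float:
    """Scoring stops at the first sepsis onset or discharge."""
    end = encounter.discharge_hour
    if encounter.truth and encounter.truth.septic and encounter.truth.onset_hour is not None:
        end = min(end, encounter.truth.onset_hour)
    return end


def prediction_hours(encounter: Encounter, config: AlertConfig) -> list[float]:
    """Integer hours in [prediction_start, monitoring_end) that are eligible."""
    end = monitoring_end(encounter)
    hours = []
    h = float(config.prediction_start)
    while h < end:
        if eligible(encounter, h, config):
            hours.append(h)
        h += 1.0
    return hours


def run_encounter(
    encounter: Encounter,
    scorer: RiskScorer,
    backend: Optional[ExtractorBackend],
    config: AlertConfig,
    retrieval_config: RetrievalConfig = RetrievalConfig(),
    catalog: Optional[SymptomCatalog] = None,
    table: Optional[LikelihoodTable] = None,
    embedder: Optional[HashingEmbedder] = None,
) -> list[AlarmRecord]:
    """Hourly alerting loop for one encounter.

    Emits a record for every direct fire and every LLM-zone adjudication
    (fired or not). Extraction is cached on the set of notes available at
    the prediction hour, so unchanged notes are not re-extracted.
    """
    if config.variant in ("ddx", "slt") and (catalog is None or table is None):
        default_catalog, default_table = ddx_mod.load_default_tables()
        catalog = catalog or default_catalog
        table = table or default_table
    embedder = embedder or HashingEmbedder()
    records: list[AlarmRecord] = []
    silenced_until = -math.inf
    extraction_cache: dict[tuple[str, ...], tuple[set[str], dict]] = {}
    end = monitoring_end(encounter)

    h = float(config.prediction_start)
    while h < end:
        if h < silenced_until or not eligible(encounter, h, config):
            h += 1.0
            continue
        score = scorer.score(encounter, h)

        if config.variant == "composer_only":
            if score >= config.composer_only_threshold:
                records.append(
                    AlarmRecord(
                        encounter_id=encounter.encounter_id,
                        hour=h,
                        zone="direct",
                        fired=True,
                        score=score,
                    )
                )
                silenced_until = h + config.silencing_hours
            h += 1.0
            continue

        action = gate(score, config)
        if action == "direct_fire":
            records.append(
                AlarmRecord(
                    encounter_id=encounter.encounter_id,
                    hour=h,
                    zone="direct",
                    fired=True,
                    score=score,
                )
            )
            silenced_until = h + config.silencing_hours
        elif action == "llm_zone":
            if backend is None:
                raise ConfigError("LLM-zone decision requires an extractor backend")
            notes = encounter.notes_until(h)
            record = AlarmRecord(
                encounter_id=encounter.encounter_id,
                hour=h,
                zone="llm_gated",
                fired=False,
                score=score,
            )
            if config.variant == "baseline":
                record.fired = baseline_decision(
                    notes, backend, config, retrieval_config, encounter.encounter_id
                )
            else:
                key = tuple(n.note_id for n in notes)
                if key not in extraction_cache:
                    extraction_cache[key] = retrieval_mod.extract_all(
                        list(catalog),
                        notes,
                        retrieval_config,
                        backend,
                        catalog=catalog,
                        embedder=embedder,
                        encounter_id=encounter.encounter_id,
                    )
                present, results = extraction_cache[key]
                result = ddx_mod.posterior(present, table, catalog)
                record.ddx_topk = ddx_mod.top_k(result, 5)
                record.bacterial_suspicion = BACTERIAL_SUSPICION in present
                record.justifications = {
                    s: r.justification for s, r in results.items() if r.present
                }
                if config.variant == "ddx":
                    record.fired = ddx_decision(
                        record.ddx_topk, record.bacterial_suspicion
                    )
                else:  # slt
                    record.fired = slt_decision(
                        result.posterior[SEVERE_SEPSIS],
                        record.bacterial_suspicion,
                        config,
                    )
            records.append(record)
            if record.fired:
                silenced_until = h + config.silencing_hours
        h += 1.0
    return records


def run_cohort(
    encounters: Sequence[Encounter],
    scorer: RiskScorer,
    backend: Optional[ExtractorBackend],
    config: AlertConfig,
    retrieval_config: RetrievalConfig = RetrievalConfig(),
    catalog: Optional[SymptomCatalog] = None,
    table: Optional[LikelihoodTable] = None,
) -> dict[str, list[AlarmRecord]]:
    """Alarm records per encounter id."""
    if config.variant in ("ddx", "slt") and (catalog is None or table is None):
        default_catalog, default_table = ddx_mod.load_default_tables()
        catalog = catalog or default_catalog
        table = table or default_table
    embedder = HashingEmbedder()
    return {
        e.encounter_id: run_encounter(
            e, scorer, backend, config, retrieval_config, catalog, table, embedder
        )
        for e in encounters
    }
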