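import math

import pytest

from edsepsis.alerts import (
    AlarmRecord,
    AlertConfig,
    ConfigError,
    ConstantScorer,
    SurrogateScorer,
    baseline_decision,
    ddx_decision,
    eligible,
    gate,
    monitoring_end,
    prediction_hours,
    run_cohort,
    run_encounter,
    slt_decision,
)
from edsepsis.cohort import CohortSpec, generate_cohort
from edsepsis.ddx import SEVERE_SEPSIS
from edsepsis.evaluation import ClinicalResponsePolicy, classify_alarms
from edsepsis.model import Encounter, NoteEvent, OrderEvent
from edsepsis.retrieval import MockLLMBackend, RetrievalConfig, canonical_phrase


def plain_encounter(discharge=14.0, orders=(), text="routine visit", severity=0.0):
    n = int(discharge)
    return Encounter(
        encounter_id="e1",
        vitals_times=[h + 0.2 for h in range(n)],
        labs_times=[h + 0.8 for h in range(0, n, 4)],
        sofa_series=[(float(h), 1) for h in range(n)],
        orders=list(orders),
        notes=[
            NoteEvent(note_id="n1", note_type="ED provider note", hour=0.5, text=text)
        ],
        discharge_hour=discharge,
        severity=severity,
    )


class TestEligible:
    def test_all_criteria_met(self):
        enc = plain_encounter()
        assert eligible(enc, 2.0, AlertConfig())

    def test_antibiotics_block_eligibility(self):
        enc = plain_encounter(
            orders=[OrderEvent(kind="iv_antibiotic_start", hour=3.0)]
        )
        assert eligible(enc, 2.0, AlertConfig())
        assert not eligible(enc, 4.0, AlertConfig())

    def test_stale_lab_half_open_boundary(self):
        enc = Encounter(
            encounter_id="e2",
            vitals_times=[h + 0.5 for h in range(40)],
            labs_times=[5.0],
            sofa_series=[(0.0, 1)],
            orders=[],
            notes=[NoteEvent(note_id="n1", note_type="ED provider note", hour=0.5, text="x")],
            discharge_hour=40.0,
        )
        assert eligible(enc, 28.0, AlertConfig())  # lab 23 h back: fresh
        assert not eligible(enc, 29.0, AlertConfig())  # exactly 24 h: half-open, stale
        assert not eligible(enc, 30.0, AlertConfig())  # lab at hour-25: stale

    def test_note_required(self):
        enc = plain_encounter()
        enc = enc.model_copy(update={"notes": []})
        assert not eligible(enc, 2.0, AlertConfig())


class TestGate:
    def test_above_theta1_fires(self):
        assert gate(0.80, AlertConfig()) == "direct_fire"

    def test_uncertainty_zone(self):
        assert gate(0.60, AlertConfig()) == "llm_zone"

    def test_boundaries_inclusive(self):
        assert gate(0.75, AlertConfig()) == "direct_fire"
        assert gate(0.50, AlertConfig()) == "llm_zone"

    def test_below_theta2(self):
        assert gate(0.49, AlertConfig()) == "no_action"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gate(1.2, AlertConfig())


class TestDecisions:
    def test_ddx_both_conditions(self):
        topk = ["a", "b", SEVERE_SEPSIS, "c", "d"]
        assert ddx_decision(topk, True)

    def test_ddx_requires_suspicion(self):
        assert not ddx_decision([SEVERE_SEPSIS], False)

    def test_ddx_requires_top5(self):
        assert not ddx_decision(["a", "b", "c", "d", "e"], True)

    def test_slt_fires_above_alpha(self):
        cfg = AlertConfig(alpha=0.5)
        assert slt_decision(0.9, True, cfg)

    def test_slt_strict_exceedance(self):
        cfg = AlertConfig(alpha=0.5)
        assert not slt_decision(0.5, True, cfg)

    def test_slt_requires_suspicion(self):
        cfg = AlertConfig(alpha=0.5)
        assert not slt_decision(0.9, False, cfg)

    def test_slt_alpha_unset(self):
        with pytest.raises(ConfigError):
            slt_decision(0.9, True, AlertConfig())

    def test_baseline_mock_fires_on_bacterial_phrase(self):
        notes = [
            NoteEvent(
                note_id="n1",
                note_type="ED provider note",
                hour=0.5,
                text=f"Exam notable for {canonical_phrase('suspicion of bacterial infection')}.",
            )
        ]
        assert baseline_decision(notes, MockLLMBackend(), AlertConfig(), RetrievalConfig())

    def test_baseline_no_fire_without_phrase(self):
        notes = [NoteEvent(note_id="n1", note_type="ED provider note", hour=0.5, text="calm")]
        assert not baseline_decision(notes, MockLLMBackend(), AlertConfig(), RetrievalConfig())


class TestRunEncounter:
    def test_constant_high_score_silencing_arithmetic(self):
        enc = plain_encounter(discharge=14.0)
        records = run_encounter(enc, ConstantScorer(0.9), None, AlertConfig(variant="ddx"))
        fired = [r.hour for r in records if r.fired]
        assert fired == [2.0, 8.0]

    def test_constant_low_score_no_alarms(self):
        enc = plain_encounter(discharge=14.0)
        records = run_encounter(enc, ConstantScorer(0.3), None, AlertConfig(variant="ddx"))
        assert records == []

    def test_llm_zone_fires_with_planted_signature(self, catalog, table):
        text = " ".join(
            f"Exam notable for {canonical_phrase(s)}."
            for s in ("fever", "elevated lactate", "suspicion of bacterial infection")
        )
        enc = plain_encounter(discharge=14.0, text=text)
        records = run_encounter(
            enc, ConstantScorer(0.6), MockLLMBackend(), AlertConfig(variant="ddx"),
            RetrievalConfig(), catalog, table,
        )
        fired = [r.hour for r in records if r.fired]
        assert fired == [2.0, 8.0]
        assert all(r.zone == "llm_gated" for r in records if r.fired)

    def test_fired_alarm_gaps_respect_silencing(self, catalog, table, small_cohort):
        alarms = run_cohort(
            small_cohort[:80],
            SurrogateScorer(),
            MockLLMBackend(),
            AlertConfig(variant="ddx"),
            RetrievalConfig(),
            catalog,
            table,
        )
        for records in alarms.values():
            hours = [r.hour for r in records if r.fired]
            assert all(b - a >= 6.0 for a, b in zip(hours, hours[1:]))

    def test_ddx_fired_set_within_gated_hours(self, catalog, table, small_cohort):
        cfg = AlertConfig(variant="ddx")
        for enc in small_cohort[:40]:
            records = run_encounter(
                enc, SurrogateScorer(), MockLLMBackend(), cfg,
                RetrievalConfig(), catalog, table,
            )
            for r in records:
                if r.fired:
                    assert gate(r.score, cfg) in ("direct_fire", "llm_zone")

    def test_composer_threshold_monotonicity_encounter_level(self, small_cohort):
        loose = AlertConfig(variant="composer_only", composer_only_threshold=0.6)
        strict = AlertConfig(variant="ddx")  # direct fires at theta1 = 0.75
        scorer = SurrogateScorer()
        for enc in small_cohort[:80]:
            loose_fired = any(r.fired for r in run_encounter(enc, scorer, None, loose))
            records = run_encounter(
                enc, scorer, MockLLMBackend(), strict, RetrievalConfig()
            )
            direct_fired = any(r.fired and r.zone == "direct" for r in records)
            if direct_fired:
                assert loose_fired

    def test_oracle_ddx_false_positives_not_above_composer(
        self, catalog, table, small_cohort
    ):
        policy = ClinicalResponsePolicy()
        comp_cfg = AlertConfig(variant="composer_only", composer_only_threshold=0.5)
        ddx_cfg = AlertConfig(variant="ddx")
        scorer = SurrogateScorer()
        comp_fp = ddx_fp = 0
        for enc in small_cohort:
            if enc.truth.septic:
                continue
            comp = run_encounter(enc, scorer, None, comp_cfg)
            dx = run_encounter(
                enc, scorer, MockLLMBackend(), ddx_cfg, RetrievalConfig(), catalog, table
            )
            comp_fp += sum(
                1 for l in classify_alarms(comp, enc.truth, policy) if l == "false"
            )
            ddx_fp += sum(
                1 for l in classify_alarms(dx, enc.truth, policy) if l == "false"
            )
        assert ddx_fp <= comp_fp


class TestSurrogateScorer:
    def test_saturation(self):
        enc = plain_encounter(severity=6.0)
        assert SurrogateScorer().score(enc, 2.0) > 0.9

    def test_midpoint(self):
        enc = plain_encounter(severity=0.0)
        assert SurrogateScorer().score(enc, 2.0) == pytest.approx(0.5)

    def test_monotone_in_severity(self):
        scorer = SurrogateScorer()
        scores = [
            scorer.score(plain_encounter(severity=s), 2.0)
            for s in [x / 4 for x in range(-20, 21)]
        ]
        assert all(b >= a for a, b in zip(scores, scores[1:]))


def test_monitoring_stops_at_onset(small_cohort):
    septic = next(e for e in small_cohort if e.truth.septic)
    assert monitoring_end(septic) == septic.truth.onset_hour
    hours = prediction_hours(septic, AlertConfig())
    assert all(h < septic.truth.onset_hour for h in hours)
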