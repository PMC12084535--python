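"""Encounter-level scoring of alarm streams under the clinical-response policy.

True alarms on septic encounters are those fired inside the closed window
``[onset - true_alarm_window, onset]``; for LLM-gated alarms severe sepsis
must additionally appear in the alarm's top-5 differentials. On non-septic
encounters a direct-fire alarm is a false alarm unconditionally, while an
LLM-gated alarm counts false only when severe sepsis is its top-1
differential — the asymmetric policy is reproduced as printed, so LLM-gated
alarms with sepsis ranked 2-5 on non-septic encounters are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .alerts import AlarmRecord, AlertConfig, prediction_hours
from .ddx import SEVERE_SEPSIS
from .model import Encounter, TruthRecord


class ClinicalResponsePolicy(BaseModel):
    model_config = ConfigDict(extra="forbid")

    true_alarm_window: float = 48.0
    min_lead: float = 0.0
    top5_tp_rule: bool = True
    top1_fp_rule: bool = True

    def model_post_init(self, __context) -> None:
        if self.true_alarm_window <= 0:
            raise ValueError("true_alarm_window must be positive")


@dataclass
class MetricsReport:
    """Encounter-level sensitivity/PPV/F1 (percent) and the false-alarm rate.

    Undefined rates (zero denominators) are reported as None, never as 0.
    """

    tp: int
    fp: int
    fn: int
    sensitivity: Optional[float]
    ppv: Optional[float]
    f1: Optional[float]
    faph: Optional[float] = None
    false_alarms: int = 0
    total_patient_hours: float = 0.0
    subgroup: Optional[str] = None

    def rounded(self, ndigits: int = 1) -> dict:
        def r(x):
            return None if x is None else round(x, ndigits)

        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity": r(self.sensitivity),
            "ppv": r(self.ppv),
            "f1": r(self.f1),
            "faph": None if self.faph is None else round(self.faph, 4),
            "false_alarms": self.false_alarms,
            "total_patient_hours": self.total_patient_hours,
            "subgroup": self.subgroup,
        }


def f1_percent(sensitivity: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and PPV, both on the percent scale."""
    if sensitivity + ppv == 0:
        return 0.0
    return 2.0 * sensitivity * ppv / (sensitivity + ppv)


def classify_alarms(
    alarms: Sequence[AlarmRecord],
    truth: TruthRecord,
    policy: ClinicalResponsePolicy = ClinicalResponsePolicy(),
) -> list[str]:
    """Per fired alarm: 'true', 'false' or 'ignored'. Unfired records are ignored."""
    labels = []
    for a in alarms:
        if not a.fired:
            labels.append("ignored")
            continue
        if truth.septic:
            if truth.onset_hour is None:
                raise ValueError("septic truth requires onset_hour")
            lo = truth.onset_hour - policy.true_alarm_window
            hi = truth.onset_hour - policy.min_lead
            in_window = lo <= a.hour <= hi
            if not in_window:
                labels.append("ignored")
            elif a.zone == "direct" or not policy.top5_tp_rule:
                labels.append("true")
            elif a.ddx_topk is not None and SEVERE_SEPSIS in a.ddx_topk[:5]:
                labels.append("true")
            else:
                labels.append("ignored")
        else:
            if a.zone == "direct" or not policy.top1_fp_rule or a.ddx_topk is None:
                labels.append("false")
            elif a.ddx_topk[0] == SEVERE_SEPSIS:
                labels.append("false")
            else:
                labels.append("ignored")
    return labels


def encounter_metrics(
    per_encounter: Iterable[tuple[Sequence[AlarmRecord], TruthRecord]],
    policy: ClinicalResponsePolicy = ClinicalResponsePolicy(),
) -> MetricsReport:
    """TP/FN over septic encounters, FP over non-septic; rates in percent."""
    tp = fp = fn = 0
    false_alarms = 0
    for alarms, truth in per_encounter:
        labels = classify_alarms(alarms, truth, policy)
        if truth.septic:
            if "true" in labels:
                tp += 1
            else:
                fn += 1
        else:
            n_false = sum(1 for l in labels if l == "false")
            false_alarms += n_false
            if n_false:
                fp += 1
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else None
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) else None
    f1 = f1_percent(sens, ppv) if (sens is not None and ppv is not None) else None
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, sensitivity=sens, ppv=ppv, f1=f1,
        false_alarms=false_alarms,
    )


def faph(false_alarm_count: int, total_patient_hours: float) -> Optional[float]:
    """False alarms divided by the total hourly prediction time points."""
    if false_alarm_count < 0 or total_patient_hours < 0:
        raise ValueError("counts must be non-negative")
    if total_patient_hours == 0:
        return None
    return false_alarm_count / total_patient_hours


def expected_unit_alarms(rate: float, beds: int, hours: float) -> float:
    """Expected alarms over ``hours`` in a unit of ``beds`` at the given FAPH."""
    if rate < 0 or beds < 0 or hours < 0:
        raise ValueError("arguments must be non-negative")
    return rate * beds * hours


def total_prediction_hours(
    encounters: Sequence[Encounter], config: AlertConfig
) -> float:
    """Sum of eligible hourly prediction time points across encounters."""
    return float(sum(len(prediction_hours(e, config)) for e in encounters))


def cohort_report(
    encounters: Sequence[Encounter],
    alarms_by_encounter: dict[str, Sequence[AlarmRecord]],
    config: AlertConfig,
    policy: ClinicalResponsePolicy = ClinicalResponsePolicy(),
    subgroup: Optional[str] = None,
) -> MetricsReport:
    """Full metrics report, including FAPH over eligible prediction hours."""
    pairs = []
    for e in encounters:
        if e.truth is None:
            raise ValueError(f"encounter {e.encounter_id} is unlabeled")
        pairs.append((alarms_by_encounter.get(e.encounter_id, []), e.truth))
    report = encounter_metrics(pairs, policy)
    report.total_patient_hours = total_prediction_hours(encounters, config)
    report.faph = faph(report.false_alarms, report.total_patient_hours)
    report.subgroup = subgroup
    return report


def suspected_infection_subgroup(
    encounters: Sequence[Encounter], window: float = 6.0
) -> list[Encounter]:
    """Encounters with a blood culture and an antibiotic start within ``window``
    hours of each other (closed at the boundary)."""
    kept = []
    for e in encounters:
        cultures = [o.hour for o in e.orders if o.kind == "blood_culture"]
        abx = [o.hour for o in e.orders if o.kind == "iv_antibiotic_start"]
        if any(abs(c - a) <= window for c in cultures for a in abx):
            kept.append(e)
    return kept
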