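"""Shared domain types for the ED sepsis alerting pipeline.

Time is expressed in hours since ED triage (hour 0) as floats. Interval
conventions are documented on the operations that use them; event containers
only enforce structural invariants (ordering, bounds).
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, model_validator

OrderKind = Literal["blood_culture", "iv_antibiotic_start", "iv_antibiotic_end"]

NoteType = Literal[
    "ED provider note",
    "History and Physical note",
    "Diagnostic image report",
    "Progress note",
]

NOTE_TYPES: tuple[str, ...] = (
    "ED provider note",
    "History and Physical note",
    "Diagnostic image report",
    "Progress note",
)


class OrderEvent(BaseModel):
    """A blood-culture draw or an IV-antibiotic start/end event."""

    kind: OrderKind
    hour: float
    prophylactic: bool = False

    @model_validator(mode="after")
    def _check(self) -> "OrderEvent":
        if self.hour < 0:
            raise ValueError("order hour must be >= 0")
        if self.prophylactic and self.kind == "blood_culture":
            raise ValueError("prophylactic flag applies to antibiotics only")
        return self


class NoteEvent(BaseModel):
    """A free-text clinical note with its type and availability time."""

    note_id: str
    note_type: NoteType
    hour: float
    text: str
    complete: bool = True


class SuspicionEvent(BaseModel):
    """A qualifying blood-culture / IV-antibiotic pairing.

    ``suspicion_hour`` is the earlier of the two order times.
    """

    suspicion_hour: float
    culture_hour: float
    abx_start_hour: float

    @model_validator(mode="after")
    def _check(self) -> "SuspicionEvent":
        expected = min(self.culture_hour, self.abx_start_hour)
        if abs(self.suspicion_hour - expected) > 1e-9:
            raise ValueError("suspicion_hour must equal min(culture_hour, abx_start_hour)")
        return self


class TruthRecord(BaseModel):
    """Ground truth attached to an encounter.

    ``symptoms`` and ``diagnosis`` are generator-side truth used for
    round-trip testing; phenotype labelling only fills ``septic``,
    ``onset_hour`` and ``suspicion``.
    """

    septic: bool
    onset_hour: Optional[float] = None
    suspicion: Optional[SuspicionEvent] = None
    symptoms: Optional[list[str]] = None
    diagnosis: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "TruthRecord":
        if self.septic and self.onset_hour is None:
            raise ValueError("septic truth requires an onset_hour")
        return self


class Encounter(BaseModel):
    """One ED stay: timed event streams, notes and optional ground truth.

    ``severity`` is a synthetic-generator latent used by the surrogate risk
    scorer; it has no meaning for real data.
    """

    encounter_id: str
    triage_time: float = 0.0
    vitals_times: list[float]
    labs_times: list[float]
    sofa_series: list[tuple[float, int]]
    orders: list[OrderEvent]
    notes: list[NoteEvent]
    discharge_hour: float
    severity: float = 0.0
    truth: Optional[TruthRecord] = None

    @model_validator(mode="after")
    def _check(self) -> "Encounter":
        if self.discharge_hour <= 0:
            raise ValueError("discharge_hour must be positive")
        for t in list(self.vitals_times) + list(self.labs_times):
            if not (0 <= t <= self.discharge_hour):
                raise ValueError("event hours must lie in [0, discharge_hour]")
        for o in self.orders:
            if not (0 <= o.hour <= self.discharge_hour):
                raise ValueError("order hours must lie in [0, discharge_hour]")
        for nt in self.notes:
            if not (0 <= nt.hour <= self.discharge_hour):
                raise ValueError("note hours must lie in [0, discharge_hour]")
        hours = [h for h, _ in self.sofa_series]
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValueError("sofa_series hours must be strictly increasing")
        if any(not (0 <= h <= self.discharge_hour) for h in hours):
            raise ValueError("sofa hours must lie in [0, discharge_hour]")
        return self

    def notes_until(self, hour: float) -> list[NoteEvent]:
        """Notes available at or before ``hour``, in (hour, note_id) order."""
        return sorted(
            (n for n in self.notes if n.hour <= hour),
            key=lambda n: (n.hour, n.note_id),
        )
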