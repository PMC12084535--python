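"""Sepsis-3 encounter phenotyping.

An encounter is septic when a qualifying suspicion-of-infection event
(blood culture paired with >= 4 days of non-prophylactic IV antibiotics
inside the 72 h / 24 h ordering windows) coincides with an acute SOFA rise
of >= 2 points inside the -48 h / +24 h dysfunction window around the
suspicion time. Onset is the first qualifying dysfunction hour.

Window conventions: order-pairing windows and the dysfunction window are
closed at both ends; the SOFA baseline is the running minimum over the
dysfunction window up to the candidate hour.
"""

from __future__ import annotations

from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .model import Encounter, OrderEvent, SuspicionEvent, TruthRecord


class PhenotypeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    abx_after_culture_window: float = 72.0
    culture_after_abx_window: float = 24.0
    min_abx_days: float = 4.0
    sofa_delta: int = 2
    dysfunction_window_before: float = 48.0
    dysfunction_window_after: float = 24.0

    @model_validator(mode="after")
    def _check(self) -> "PhenotypeConfig":
        for f in (
            "abx_after_culture_window",
            "culture_after_abx_window",
            "min_abx_days",
            "dysfunction_window_before",
            "dysfunction_window_after",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.sofa_delta < 1:
            raise ValueError("sofa_delta must be >= 1")
        return self


def _abx_episodes(orders: Sequence[OrderEvent]) -> list[tuple[float, float, bool]]:
    """Pair antibiotic start events with the next end event after each start."""
    starts = sorted(
        (o for o in orders if o.kind == "iv_antibiotic_start"), key=lambda o: o.hour
    )
    ends = sorted(o.hour for o in orders if o.kind == "iv_antibiotic_end")
    episodes = []
    used: set[int] = set()
    for s in starts:
        end = None
        for i, e in enumerate(ends):
            if i not in used and e > s.hour:
                end = e
                used.add(i)
                break
        if end is not None:
            episodes.append((s.hour, end, s.prophylactic))
    return episodes


def find_suspicion_events(
    orders: Sequence[OrderEvent], config: PhenotypeConfig = PhenotypeConfig()
) -> list[SuspicionEvent]:
    """All qualifying (culture, antibiotic-episode) pairings.

    An episode qualifies when non-prophylactic and lasting at least
    ``min_abx_days``; the pairing qualifies when culture-first with the
    antibiotic start within ``abx_after_culture_window`` hours, or
    antibiotic-first with the culture within ``culture_after_abx_window``
    hours (both windows closed).
    """
    cultures = sorted(o.hour for o in orders if o.kind == "blood_culture")
    min_hours = config.min_abx_days * 24.0
    episodes = [
        (start, end)
        for start, end, prophylactic in _abx_episodes(orders)
        if not prophylactic and (end - start) >= min_hours
    ]
    events = []
    seen: set[tuple[float, float]] = set()
    for c in cultures:
        for start, _end in episodes:
            if c <= start:
                ok = (start - c) <= config.abx_after_culture_window
            else:
                ok = (c - start) <= config.culture_after_abx_window
            if ok and (c, start) not in seen:
                seen.add((c, start))
                events.append(
                    SuspicionEvent(
                        suspicion_hour=min(c, start), culture_hour=c, abx_start_hour=start
                    )
                )
    events.sort(key=lambda e: (e.suspicion_hour, e.culture_hour, e.abx_start_hour))
    return events


def assign_onset(
    sofa_series: Sequence[tuple[float, int]],
    suspicion: SuspicionEvent,
    config: PhenotypeConfig = PhenotypeConfig(),
) -> Optional[float]:
    """First hour in the dysfunction window with a SOFA rise >= ``sofa_delta``.

    The rise is measured against the running minimum of the series from the
    window start up to the candidate hour; both window edges are included.
    """
    if not sofa_series:
        raise ValueError("sofa_series must be non-empty")
    lo = suspicion.suspicion_hour - config.dysfunction_window_before
    hi = suspicion.suspicion_hour + config.dysfunction_window_after
    running_min: Optional[int] = None
    for t, v in sofa_series:
        if t < lo or t > hi:
            continue
        if running_min is None or v < running_min:
            running_min = v
        if v - running_min >= config.sofa_delta:
            return t
    return None


def label_encounter(
    encounter: Encounter, config: PhenotypeConfig = PhenotypeConfig()
) -> TruthRecord:
    """Septic iff some suspicion event has a qualifying onset; earliest onset wins."""
    best: Optional[tuple[float, SuspicionEvent]] = None
    for ev in find_suspicion_events(encounter.orders, config):
        onset = assign_onset(encounter.sofa_series, ev, config)
        if onset is not None and (best is None or onset < best[0]):
            best = (onset, ev)
    if best is None:
        return TruthRecord(septic=False)
    return TruthRecord(septic=True, onset_hour=best[0], suspicion=best[1])
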