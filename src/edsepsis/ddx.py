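"""Naive-Bayes differential diagnosis over severe sepsis and 18 mimics.

The posterior over the closed 19-condition set is computed from the set of
clinical signs judged *present*:

    P(D | CS) = P(D) * prod_i P(CS_i = 1 | D) / P(CS)

where the product runs over the present signs that are mapped to condition D
and the evidence P(CS) normalizes over the condition set. Absent or unknown
signs contribute no factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

SEVERE_SEPSIS = "Severe Sepsis"
BACTERIAL_SUSPICION = "suspicion of bacterial infection"

_LIK_FLOOR = 0.01
_LIK_CEIL = 0.99


class CatalogError(KeyError):
    """A symptom name that is not in the catalog."""


class DegenerateEvidenceError(ValueError):
    """All posterior numerators vanished; no normalization possible."""


class CalibrationError(ValueError):
    """The development cohort cannot support calibration."""


@dataclass(frozen=True)
class SymptomCatalog:
    """Ordered, unique list of clinical sign/symptom names."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("catalog names must be unique")

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def validate(self, names: Iterable[str]) -> None:
        unknown = [n for n in names if n not in self.names]
        if unknown:
            raise CatalogError(f"unknown symptom(s): {unknown}")


@dataclass(frozen=True)
class DiseaseSet:
    """Ordered set of conditions in the differential."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("disease names must be unique")

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class LikelihoodTable:
    """Per-condition sign likelihoods, priors and sign maps.

    ``lik[d][s]`` is P(sign s present | condition d); its keys define the
    sign map of d. ``prior`` defaults to uniform over ``diseases``.
    """

    diseases: DiseaseSet
    lik: Mapping[str, Mapping[str, float]]
    prior: Mapping[str, float]

    def __post_init__(self) -> None:
        for d in self.diseases:
            if d not in self.lik:
                raise ValueError(f"missing likelihood row for {d!r}")
            for s, p in self.lik[d].items():
                if not (0.0 < p < 1.0):
                    raise ValueError(f"likelihood for ({d!r}, {s!r}) must be in (0,1)")
        total = sum(self.prior[d] for d in self.diseases)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")

    def symptom_map(self, disease: str) -> frozenset[str]:
        return frozenset(self.lik[disease])

    def with_row(self, disease: str, row: Mapping[str, float]) -> "LikelihoodTable":
        lik = {d: dict(v) for d, v in self.lik.items()}
        lik[disease] = dict(row)
        return replace(self, lik=lik)


@dataclass(frozen=True)
class DdxResult:
    """Posterior over the condition set and the ranked differential list."""

    posterior: dict[str, float]
    evidence: float
    ranked: list[str]


def load_default_tables() -> tuple[SymptomCatalog, LikelihoodTable]:
    """Load the shipped 51-sign catalog and 19-condition likelihood table."""
    raw = yaml.safe_load(
        resources.files("edsepsis.data").joinpath("ddx_default.yaml").read_text()
    )
    catalog = SymptomCatalog(tuple(raw["symptoms"]))
    diseases = DiseaseSet(tuple(raw["diseases"]))
    prior = raw.get("priors") or {d: 1.0 / len(diseases) for d in diseases}
    lik = {d: dict(raw["likelihoods"][d]) for d in diseases}
    for d, row in lik.items():
        catalog.validate(row)
    return catalog, LikelihoodTable(diseases=diseases, lik=lik, prior=prior)


def joint_log_likelihood(
    present: Iterable[str], disease: str, table: LikelihoodTable,
    catalog: Optional[SymptomCatalog] = None,
    absence_terms: bool = True,
) -> float:
    """Log joint likelihood of the present-set under ``disease``.

    With ``absence_terms`` (the default) this is binary naive Bayes over the
    M signs mapped to the condition: present signs contribute ``log p`` and
    absent mapped signs contribute ``log(1 - p)``. With
    ``absence_terms=False`` only present signs contribute, so the empty (or
    disjoint) present-set yields 0.0 — under that reading a condition with
    no matching signs scores the empty product 1 and dominates the ranking,
    which is why the absence terms are the default.
    """
    present = set(present)
    if catalog is not None:
        catalog.validate(present)
    row = table.lik[disease]
    if not absence_terms:
        return sum(math.log(row[s]) for s in present if s in row)
    return sum(
        math.log(p) if s in present else math.log1p(-p) for s, p in row.items()
    )


def posterior(
    present: Iterable[str], table: LikelihoodTable,
    catalog: Optional[SymptomCatalog] = None,
    absence_terms: bool = True,
) -> DdxResult:
    """Normalized posterior over the condition set, ranked descending.

    Ties are broken by lexicographic condition name so the ranking is a
    deterministic permutation of the condition set.
    """
    present = set(present)
    numer_log = {}
    for d in table.diseases:
        p = table.prior[d]
        if p <= 0.0:
            numer_log[d] = -math.inf
        else:
            numer_log[d] = math.log(p) + joint_log_likelihood(
                present, d, table, catalog, absence_terms
            )
    finite = [v for v in numer_log.values() if v > -math.inf]
    if not finite:
        raise DegenerateEvidenceError("all posterior numerators are zero")
    shift = max(finite)
    numer = {d: (math.exp(v - shift) if v > -math.inf else 0.0) for d, v in numer_log.items()}
    z = sum(numer.values())
    post = {d: v / z for d, v in numer.items()}
    ranked = sorted(post, key=lambda d: (-post[d], d))
    return DdxResult(posterior=post, evidence=z * math.exp(shift), ranked=ranked)


def top_k(result: DdxResult, k: int) -> list[str]:
    """First ``k`` conditions of the ranked differential."""
    if not (1 <= k <= len(result.ranked)):
        raise ValueError(f"k must be in [1, {len(result.ranked)}]")
    return result.ranked[:k]


def sepsis_likelihood(
    present: Iterable[str], table: LikelihoodTable,
    catalog: Optional[SymptomCatalog] = None,
    absence_terms: bool = True,
) -> float:
    """Posterior mass assigned to severe sepsis."""
    return posterior(present, table, catalog, absence_terms).posterior[SEVERE_SEPSIS]


# --------------------------------------------------------------------------
# Calibration


@dataclass(frozen=True)
class CalibrationRecord:
    """One development encounter: extracted present-set plus labels."""

    present: frozenset[str]
    septic: bool
    diagnosis: Optional[str] = None


@dataclass(frozen=True)
class SearchSpec:
    """Budget/seed for the seeded likelihood search."""

    budget: int = 200
    seed: int = 0
    step: float = 0.15
    estimate_from_diagnoses: bool = True


def alert_f1(table: LikelihoodTable, records: Sequence[CalibrationRecord]) -> float:
    """Encounter-level F1 of the top-5 + bacterial-suspicion alert rule."""
    tp = fp = fn = 0
    for r in records:
        fire = (
            BACTERIAL_SUSPICION in r.present
            and SEVERE_SEPSIS in top_k(posterior(r.present, table), 5)
        )
        if fire and r.septic:
            tp += 1
        elif fire:
            fp += 1
        elif r.septic:
            fn += 1
    if tp == 0:
        return 0.0
    sens = tp / (tp + fn)
    ppv = tp / (tp + fp)
    return 2 * sens * ppv / (sens + ppv)


def _empirical_table(
    table: LikelihoodTable, records: Sequence[CalibrationRecord]
) -> LikelihoodTable:
    """Per-condition sign frequencies among records with that true diagnosis."""
    out = table
    by_dx: dict[str, list[frozenset[str]]] = {}
    for r in records:
        dx = SEVERE_SEPSIS if r.septic else r.diagnosis
        if dx is not None and dx in table.lik:
            by_dx.setdefault(dx, []).append(r.present)
    for d, sets in by_dx.items():
        n = len(sets)
        row = {
            s: min(_LIK_CEIL, max(_LIK_FLOOR, sum(s in ps for ps in sets) / n))
            for s in table.lik[d]
        }
        out = out.with_row(d, row)
    return out


def calibrate(
    records: Sequence[CalibrationRecord],
    initial: LikelihoodTable,
    spec: SearchSpec = SearchSpec(),
) -> LikelihoodTable:
    """Fit sign likelihoods on a development cohort.

    With a positive budget the search seeds itself from per-diagnosis
    empirical sign frequencies (when true diagnoses are available) and then
    runs a seeded random local search over single likelihood entries,
    accepting moves that strictly improve the downstream alert F1. Entries
    stay inside (0.01, 0.99). A zero budget returns ``initial`` unchanged.
    """
    if spec.budget <= 0:
        return initial
    if not any(r.septic for r in records) or not any(not r.septic for r in records):
        raise CalibrationError("development cohort needs septic and non-septic encounters")

    best = initial
    best_f1 = alert_f1(best, records)
    if spec.estimate_from_diagnoses and any(
        r.diagnosis is not None or r.septic for r in records
    ):
        cand = _empirical_table(initial, records)
        f1 = alert_f1(cand, records)
        if f1 >= best_f1:  # prefer the data-driven table on ties
            best, best_f1 = cand, f1

    rng = np.random.default_rng(spec.seed)
    diseases = list(best.diseases)
    for _ in range(spec.budget):
        d = diseases[rng.integers(len(diseases))]
        row = dict(best.lik[d])
        s = sorted(row)[rng.integers(len(row))]
        prop = row[s] + rng.normal(0.0, spec.step)
        row[s] = min(_LIK_CEIL, max(_LIK_FLOOR, float(prop)))
        cand = best.with_row(d, row)
        f1 = alert_f1(cand, records)
        if f1 > best_f1:
            best, best_f1 = cand, f1
    return best


def pairwise_ordering_agreement(
    truth: LikelihoodTable, fitted: LikelihoodTable
) -> float:
    """Fraction of within-row likelihood-ordering pairs preserved by ``fitted``."""
    agree = total = 0
    for d in truth.diseases:
        names = sorted(truth.lik[d])
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                ta, tb = truth.lik[d][a], truth.lik[d][b]
                fa, fb = fitted.lik[d][a], fitted.lik[d][b]
                if ta == tb:
                    continue
                total += 1
                if (ta - tb) * (fa - fb) > 0:
                    agree += 1
    return agree / total if total else 1.0
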