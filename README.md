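# edsepsis

Uncertainty-gated early sepsis alerting for emergency-department encounters,
with a retrieval-based clinical-sign extractor and a naive-Bayes differential
diagnosis engine over severe sepsis and 18 sepsis-mimics — exercised
end-to-end on a fully synthetic ED cohort so every stage is testable without
any real patient data.

## What it does

- **`edsepsis.cohort`** — synthetic ED cohort generator: hourly vitals/labs
  timelines, blood-culture and IV-antibiotic order events, SOFA trajectories,
  and clinical notes with planted canonical phrases for each encounter's true
  present-sign set. Deterministic from a seed.
- **`edsepsis.phenotype`** — Sepsis-3 encounter phenotyping: qualifying
  culture/antibiotic suspicion pairings (72 h / 24 h ordering windows, ≥4 days
  of non-prophylactic IV therapy) combined with a SOFA rise ≥2 inside the
  −48 h/+24 h dysfunction window; onset is the first qualifying dysfunction
  hour.
- **`edsepsis.retrieval`** — note chunking (1000-token windows, 300-token
  overlap), hashed bag-of-words retrieval (top-K = 5 by cosine similarity),
  and a pluggable extractor backend with three-run majority voting and
  fail-safe JSON parsing. A deterministic mock backend keyed on the phrase
  lexicon is the tested path; real LLM backends are adapters behind the same
  interface.
- **`edsepsis.ddx`** — naive-Bayes posteriors over the 19-condition set from
  the extracted present-sign set, ranked differentials, and seeded
  calibration of the sign-likelihood table against the downstream alert F1.
- **`edsepsis.alerts`** — the hourly decision loop: eligibility, two-threshold
  risk-score gating (θ₁ = 0.75 direct fire; θ₂ = 0.5 ≤ score < θ₁ adjudicated
  by the note-derived differential), four alert variants (`ddx`, `slt`,
  `baseline`, `composer_only`) and a 6-hour silencing policy.
- **`edsepsis.evaluation`** — encounter-level sensitivity/PPV/F1 under the
  48-hour clinical-response policy, false alarms per patient-hour (FAPH),
  care-unit alarm-burden conversions, and the suspected-infection subgroup
  filter.
- **`edsepsis.config` / `edsepsis.cli`** — validated YAML configuration and a
  single `edsepsis` entry point orchestrating synth → phenotype → run →
  evaluate.

## CLI

```sh
edsepsis synth-cohort --n 2000 --septic-fraction 0.166 --seed 1 --out cohort.jsonl
edsepsis phenotype --cohort cohort.jsonl --out labels.csv
edsepsis ddx --symptoms "fever,suspicion of bacterial infection" --k 5
edsepsis run --cohort cohort.jsonl --variant ddx --alarms-out alarms.jsonl
edsepsis evaluate --alarms alarms.jsonl --labels labels.csv --cohort cohort.jsonl --report report.json
edsepsis experiment --n 2000 --seed 1 --out results/
```

`experiment` generates a cohort, splits it 30/70 into development and
validation, calibrates the likelihood table and the SLT threshold on the
development split, runs all four variants on the validation split, and writes
per-variant metric reports plus alarm audit logs.

## Data defaults

The 51-sign catalog, the 19-condition set, and the default sign-likelihood
table ship as editable YAML (`src/edsepsis/data/ddx_default.yaml`). The
per-condition sign assignment is configuration curated from standard clinical
descriptions, not ground truth; priors default to uniform.
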