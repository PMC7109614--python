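# copdflow

Decision support for the **early diagnosis of chronic obstructive pulmonary
disease (COPD)** in primary care, built as an executable, fully traceable
clinical process rather than a bag of calculators.

COPD is heavily underdiagnosed: patients present for unrelated reasons while
their airflow limitation goes unmeasured, spirometry is often performed or
interpreted poorly, and referral criteria are applied inconsistently.
`copdflow` implements a redesigned diagnostic pathway as a state machine that
an engine can drive end to end:

1. **Opportunistic screening** — when any patient strictly over 40 books an
   appointment, the nightly sweep invites them to a short screening
   questionnaire, unless they completed one within the last 2 years. A
   positive screen alerts both patient and doctor before the visit, and a
   reminder is scheduled exactly 24 h before the appointment.
2. **Spirometry validation** — the device must be calibrated (≤ 24 h old),
   maneuvers flagged for slow start, early termination (FET < 6 s), glottis
   closure or variable effort are excluded, and the session is reproducible
   only if the two best FVC and the two best FEV1 values (of ≥ 3 acceptable
   attempts) differ by ≤ 0.15 L each.
3. **Obstruction call** — on the best-values ratio FEV1/FVC, either against
   the guideline fixed cut (ratio < 0.70) or, by default, against the
   patient's **lower limit of normal (LLN)** from reference equations in age,
   sex, height and ancestry group — avoiding the overdiagnosis the fixed cut
   produces in the elderly, whose normal ratio drifts below 0.70.
4. **Severity staging and referral** — BODE (BMI, obstruction as FEV1 %
   predicted, mMRC dyspnea, 6-minute walk; 0–10) and/or BODEx (exacerbations
   replacing the walk; 0–9) map to four severity levels, CAT (0–40) to four
   impact levels; severe/very severe disease or frequent exacerbations
   (≥ 2/yr or ≥ 1 hospitalization) trigger a specialist referral with a
   mandatory structured report.
5. **Differential diagnosis** — a seven-disease feature knowledge base
   (asthma, heart failure, bronchiectasis, tuberculosis, obliterative
   bronchiolitis, diffuse panbronchiolitis, COPD itself) ranked by Jaccard
   overlap with the observed presentation, with matched features listed for
   explainability.

Every step is a state with a responsible actor (patient/doctor/nurse/system)
and entry/exit timestamps, so per-task durations and full audit trails come
for free. All clinical constants (age cut, windows, 0.15 L, 0.70, cut-point
tables, the screening instrument, the reference equations) are configuration
and auditable data files, not code.

A synthetic-cohort generator with known obstruction ground truth makes the
whole pathway testable without patient data: true FEV1/FVC ratios are placed
relative to each synthetic patient's own LLN, attempts get controllable
within-session noise, and screening answers are sampled to target a chosen
sensitivity/specificity.

## Worked example

Simulate the bundled demo cohort (50 synthetic patients, seed 7) and replay
every patient through the full process:

```bash
copdflow simulate
```

```json
{
  "n": 50,
  "seed": 7,
  "confusion": { "tp": 16, "fp": 0, "fn": 0, "tn": 28 },
  "sensitivity": 1.0,
  "specificity": 1.0,
  "screening_uptake": 1.0,
  "referral_rate": 0.625,
  "first_session_invalid_fraction": 0.0,
  "mean_time_to_terminal_days": 12.361562007825926,
  "terminal_states": {
    "copd_diagnosed_primary_care": 6,
    "no_show": 6,
    "not_copd": 28,
    "referred_to_specialist": 10
  }
}
```

Reading this: 44 of the 50 patients attended (6 no-shows hit the terminal
`no_show` state); the engine's LLN-based obstruction calls matched ground
truth for all 44 (16 true positives, 28 true negatives); 10 of the 16
diagnosed patients met the referral rule (62.5 %), the other 6 were staged
and treated in primary care; the mean journey from appointment request to a
terminal state took ~12.4 days.

The other subcommands operate on single records, e.g. scoring a screening
questionnaire:

```bash
copdflow screen answers.json
# stderr: screening POSITIVE: 6/10 (cutoff 5)
```

and `spiro`, `stage`, `differential`, `run` (full task-log dump as JSON
Lines) and `report` (per-task duration table) cover the remaining steps.
Library use mirrors the CLI: see `copdflow.spirometry.interpret_session`,
`copdflow.staging.stage_patient`, `copdflow.process.advance`,
`copdflow.cohort.generate_cohort` / `end_to_end_replay`.

## Scope

`copdflow` is an engine, not a medical device: it encodes published rules and
ships replaceable data files for every clinical constant. The bundled
screening instrument and severity band tables are explicitly non-canonical
defaults (see `docs/methods.md`), notifications are in-memory artifacts, and
no EHR, device or messaging integration is included.
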