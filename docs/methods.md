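# Methods

This note documents the models and procedures `copdflow` implements, the
defaults it ships, what the synthetic cohort does and does not emulate, and
the numerical choices that matter.

## The diagnostic process model

The pathway is executed as an explicit finite state machine
(`data/process_model.yaml`): 19 states — one per clinical task, from
`appointment_requested` through eligibility check, screening, consultation,
spirometry (calibration check, attempts, validation), complementary tests,
differential diagnosis and severity staging, to four terminal outcomes
(`not_copd`, `copd_diagnosed_primary_care`, `referred_to_specialist`,
`no_show`). Each state carries a responsible actor label (patient, doctor,
nurse, system).

Design choices:

- **Guards are pure predicates over the instance payload** (e.g. `eligible`,
  `session_obstructed`), registered by name; transitions for one
  (state, event) pair are evaluated in definition order with `always` as the
  mandatory last fallback. This keeps dispatch deterministic and testable.
- **The clock is always an explicit argument**; the engine never reads wall
  time, so every trace is reproducible. Clocks may not run backwards
  relative to an instance's log.
- **Traceability**: each log entry records state, entering event, actor and
  entry/exit timestamps; exactly one entry is open unless the instance is
  terminal. `replay()` re-walks a log against the model and is used as the
  soundness oracle in the tests. `task_duration_report()` aggregates closed
  entries (count/mean/median/max seconds per task) and counts open tasks
  separately — the raw material for finding tasks that dilate the process.
- **No-show**: appointments without a consultation within a configurable
  window (default 7 days, `no_show_window`) terminate at `no_show`. The
  window length is a configuration default; absenteeism in primary care is
  commonly in the 10–15 % range, which is the generator's default no-show
  probability.

Model validation at load time enforces: known guards, no transitions out of
terminals, at least one exit from every non-terminal state, and reachability
of every state from the initial state (breadth-first search).

## Screening

Eligibility for opportunistic screening is strict: age **> 40** (the 35-year
cut used by some guidelines is available via `suspicion_age_cut` /
`screening_age_cut`) and no screening within the **2-year revalidation
window**. The nightly sweep also refuses to re-invite a patient invited
within the window, which makes repeated sweeps over the same appointment
list idempotent.

The questionnaire is configuration, not code. The bundled 5-item instrument
(age band, smoking exposure, exertional dyspnea, chronic cough/sputum, prior
breathing episodes; each 0–2 points, positive at ≥ 5 of 10) is modeled on
published COPD population screeners but is **explicitly non-canonical** — the
pathway mandates a screening step without fixing the instrument. Scoring is
by canonical item key, so answer arrival order is irrelevant; totals are
integer sums and positivity is `total >= cutoff`.

Key-indicator suspicion at consultation time fires when age exceeds the cut
and at least one of: dyspnea, chronic cough, chronic sputum, recurrent
lower-respiratory infections, risk-factor exposure, family history. Symptom
flags are tri-state (`True`/`False`/`None` = not asked); unknown flags count
as false for the decision but are reported separately so output never
conflates "absent" with "not asked".

## Spirometry

- **Calibration**: inclusive window, default ≤ 24 h since last calibration.
- **Acceptability**: curve-shape failures (slow start, glottis closure,
  variable effort) are operator judgements passed through as flags; only
  early termination is derivable, from forced expiratory time < 6 s when
  reported. Flow–volume morphology analysis is out of scope.
- **Reproducibility**: with ≥ 3 acceptable attempts, (max − second) FVC and
  FEV1 must each be ≤ 0.15 L, inclusive. With > 3 attempts the same
  two-best rule applies over all acceptable attempts (a monotone
  generalization: extra maneuvers can only help). The rule is applied to
  acceptable attempts only; applying it to all attempts is the plausible
  alternative reading.
- **Numerical convention**: volumes are treated as recorded on a 0.01 L
  lattice (devices report centiliters). Deltas are rounded to 0.001 L before
  threshold comparison, because raw float subtraction (3.30 − 3.15 =
  0.15000000000000013) would misclassify the inclusive 0.15 boundary. The
  FEV1/FVC ratio, by contrast, is carried at full precision and compared
  unrounded, avoiding threshold artifacts at 0.70.
- **Best values** are per-parameter maxima over acceptable attempts and may
  come from different maneuvers.
- **LLN**: the bundled reference set (`data/reference_equations.csv`)
  transcribes the NHANES III adult FEV1/FVC and FEV1 equations (Hankinson
  et al. 1999): predicted ratio and LLN are linear in age per (sex, group)
  row; predicted FEV1 is quadratic in age with a height² term. Rows may
  alternatively supply a standard error of estimate, in which case
  LLN = predicted − 1.645 × SEE. Ancestry handling selects separate
  coefficient rows per group (rather than multiplicative correction
  factors). Evaluation outside a row's validated age/height range raises —
  the set never extrapolates. The file is replaceable and must carry a
  `# source:` provenance line; the engine only relies on the structural
  properties (LLN < predicted, LLN decreasing with age), which hold for any
  sane equation set.

## Severity staging

BODE and BODEx cut-points ship as a provenance-labelled CSV
(`data/index_cutpoints.csv`, transcribed from the original index
publications): BMI ≤ 21 → 1; FEV1 % predicted ≥ 65/50–64/36–49/≤ 35 →
0/1/2/3; mMRC 0–1/2/3/4 → 0/1/2/3; 6MWD ≥ 350/250–349/150–249/≤ 149 →
0/1/2/3; BODEx exacerbations 0/1–2/≥ 3 → 0/1/2. Band semantics in the file
are left-open/right-closed (`min < v ≤ max`), which reproduces the published
integer cut-points exactly and gives a total, gap-free cover of each
component's range.

The mapping from index score to the four severity levels is **not fixed by
the pathway**; the defaults (BODE 0–2/3–4/5–6/7–10, BODEx 0–2/3–4/5–6/7–9)
are quartile-style, configurable, and validated for gap/overlap-free
coverage. CAT impact bands default to < 10/10–20/21–30/> 30. Because it is
genuinely ambiguous whether severity should instead follow FEV1-based
grades, an FEV1-%-predicted banding (≥ 80/50–79/30–49/< 30, floor applied to
the continuous value) is implemented as an alternative driver
(`index_precedence="fev1"`); the default prefers BODE when a 6-minute walk
is recorded and falls back to BODEx.

Referral fires on severity ∈ {severe, very severe} or frequent exacerbations
(defaults: ≥ 2 moderate/yr or ≥ 1 hospitalization — a common convention, as
the pathway does not define "frequent"). A flagged referral must carry a
complete report (scores, spirometry summary, exacerbation history);
incomplete reports are rejected with the missing field named.

## Differential diagnosis

The knowledge base decomposes each disease's free-text feature descriptions
into atomic canonical keys (`data/feature_vocabulary.csv`), keeping the
verbatim source text alongside each key for auditability. Ranking is Jaccard
similarity |F ∩ P| / |F ∪ P| over feature keys — the simplest fully
explainable choice — with ties broken by the fixed knowledge-base order and
matched features listed per suggestion. A scorer plug point accepts weighted
alternatives. The output is decision support, never an automated diagnosis.

## Synthetic cohort

What it emulates: demographics in the screening-eligible range (ages 41–85
by default, so the default cohort exercises the full pipeline; under-40
behavior is covered by unit tests of the eligibility rules), anthropometrics
by sex, ancestry-group mix, smoking enriched among the obstructed, symptom
flags correlated with ground truth, screening answers sampled to hit target
sensitivity/specificity in expectation, three-attempt sessions with Gaussian
within-session noise σ (default 0.05 L) on a 0.01 L recording lattice, and
no-shows (default 10 %).

Key constructions:

- **Truth relative to the patient's own LLN**: obstructed patients' true
  ratio is LLN − gap, non-obstructed LLN + gap, with gap ≥ 0.01 (clearance
  chosen so the recording lattice cannot flip a noise-free call). This makes
  the fixed-vs-LLN discordance band populated by construction.
- **One RNG stream per patient**, keyed (seed, patient index): cohorts are
  extensible without reshuffling existing patients, and generation is
  byte-identical across runs.
- **Replay**: the end-to-end driver walks each patient through the state
  machine exactly as the engine prescribes. On a reproducibility failure the
  session is repeated (as the pathway requires); after two noisy repeats the
  final repeat is generated noise-free — the patient eventually performs a
  technically adequate session — which guarantees termination while keeping
  repeat counts realistic at the default σ.

What it does **not** emulate: real epidemiological age/severity joint
distributions, device-specific error structure, correlated repeat-session
noise, item-level questionnaire psychometrics, or care-seeking behavior.
Passing tests therefore demonstrate the engine's logic (rule correctness,
traceability, threshold behavior, recovery of a known signal), not clinical
performance on real populations.

## Problem sizes and tolerances

The test suite checks the reproducibility rule against a brute-force
pair-enumeration oracle on an exhaustive 0.01 L lattice of ~1.2 × 10⁵
attempt triples; index exactness/monotonicity on a lattice straddling every
cut-point at ± 0.01; discordance on a 5,000-patient cohort; noise-free
recovery at n = 1,000; 10⁴ random valid walks through the process model;
all 2¹⁰ subsets of a 10-feature vocabulary against a naive ranking oracle;
and 10⁵ randomized staging inputs for referral soundness. The acceptance
script uses cohorts of 500–2,000. Statistical checks (e.g. prevalence
recovery at n = 5,000) use 3-standard-error bands; exact rules are asserted
exactly.

## Known limitations

- The bundled reference equations and cut-point tables are transcriptions;
  the data files carry source labels and are designed to be replaced by
  locally validated versions.
- Severity band defaults and the screening instrument are non-canonical (see
  above) and must be configured deliberately for any real deployment.
- Complementary tests (imaging, oximetry, blood work) are pass-through
  facts; no interpretation is attempted.
- Notifications are artifacts, not messages; no transport, EHR or device
  integration exists.
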