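# Bundled diagnostic process model: one state per task of the redesigned
# COPD pathway, from appointment request through screening, consultation,
# spirometry, differential diagnosis and staging to one of four terminal
# outcomes.  Guards are names of pure predicates registered in
# copdflow.process.GUARDS; they read only the instance payload.
initial: appointment_requested
states:
  appointment_requested: {actor: patient}
  eligibility_check: {actor: system}
  screening_invited: {actor: patient}
  suspicion_recorded: {actor: system}
  awaiting_consultation: {actor: patient}
  consultation_evaluation: {actor: doctor}
  calibration_check: {actor: system}
  spirometer_calibration: {actor: nurse}
  spirometry_attempts: {actor: nurse}
  spirometry_validation: {actor: system}
  complementary_tests: {actor: doctor}
  differential_diagnosis: {actor: doctor}
  severity_staging: {actor: system}
  referral_report: {actor: doctor}
  treatment_planning: {actor: doctor}
  not_copd: {actor: system, terminal: true}
  copd_diagnosed_primary_care: {actor: doctor, terminal: true}
  referred_to_specialist: {actor: doctor, terminal: true}
  no_show: {actor: system, terminal: true}
transitions:
  - {from: appointment_requested, event: appointment_registered, guard: always, to: eligibility_check}
  - from: eligibility_check
    event: eligibility_checked
    guard: eligible
    to: screening_invited
    notify:
      - {recipient: patient, kind: screening_invite, payload_key: screening_invite}
  - {from: eligibility_check, event: eligibility_checked, guard: always, to: awaiting_consultation}
  - from: screening_invited
    event: screening_done
    guard: screening_positive
    to: suspicion_recorded
    notify:
      - {recipient: patient, kind: screening_positive_alert, payload_key: probable_copd_patient}
      - {recipient: doctor, kind: screening_positive_alert, payload_key: probable_copd_doctor}
  - {from: screening_invited, event: screening_done, guard: always, to: awaiting_consultation}
  - {from: screening_invited, event: screening_skipped, guard: always, to: awaiting_consultation}
  - {from: suspicion_recorded, event: suspicion_logged, guard: always, to: awaiting_consultation}
  - {from: awaiting_consultation, event: consultation_started, guard: always, to: consultation_evaluation}
  - {from: awaiting_consultation, event: no_show_timeout, guard: always, to: no_show}
  - {from: consultation_evaluation, event: evaluation_done, guard: copd_suspected, to: calibration_check}
  - {from: consultation_evaluation, event: evaluation_done, guard: always, to: not_copd}
  - {from: calibration_check, event: calibration_checked, guard: calibrated, to: spirometry_attempts}
  - {from: calibration_check, event: calibration_checked, guard: always, to: spirometer_calibration}
  - {from: spirometer_calibration, event: calibration_performed, guard: always, to: spirometry_attempts}
  - {from: spirometry_attempts, event: attempts_recorded, guard: always, to: spirometry_validation}
  - {from: spirometry_validation, event: session_assessed, guard: session_invalid, to: spirometry_attempts}
  - {from: spirometry_validation, event: session_assessed, guard: session_obstructed, to: complementary_tests}
  - {from: spirometry_validation, event: session_assessed, guard: always, to: not_copd}
  - {from: complementary_tests, event: tests_reviewed, guard: always, to: differential_diagnosis}
  - {from: differential_diagnosis, event: differential_done, guard: copd_confirmed, to: severity_staging}
  - {from: differential_diagnosis, event: differential_done, guard: always, to: not_copd}
  - {from: severity_staging, event: staging_done, guard: refer, to: referral_report}
  - {from: severity_staging, event: staging_done, guard: always, to: treatment_planning}
  - {from: referral_report, event: report_completed, guard: always, to: referred_to_specialist}
  - {from: treatment_planning, event: treatment_defined, guard: always, to: copd_diagnosed_primary_care}
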