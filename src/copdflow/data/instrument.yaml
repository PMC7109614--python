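# Default screening questionnaire.
# NON-CANONICAL: the redesigned pathway requires *an* initial screening but
# does not fix the instrument.  This 5-item screener is modeled on published
# COPD population screeners (age, smoking exposure, exertional dyspnea,
# productive cough, prior breathing episodes) and is fully replaceable:
# point EngineConfig.instrument_path at your own definition.
name: copdflow-default-5item
source: "copdflow bundled default, modeled on published COPD population screeners; non-canonical"
cutoff: 5
items:
  - key: age_band
    text: "Age band (0: 41-49, 1: 50-59, 2: 60+)"
    scores: {0: 0, 1: 1, 2: 2}
  - key: pack_years_band
    text: "Smoking exposure (0: <10 pack-years, 1: 10-19, 2: 20+)"
    scores: {0: 0, 1: 1, 2: 2}
  - key: dyspnea_exertion
    text: "Short of breath on exertion (0: never, 1: hurrying/uphill, 2: at own pace on level ground)"
    scores: {0: 0, 1: 1, 2: 2}
  - key: cough_sputum
    text: "Chronic cough or sputum production (0: no, 1: occasionally, 2: most days)"
    scores: {0: 0, 1: 1, 2: 2}
  - key: prior_episodes
    text: "Prior episodes of breathing problems / lower respiratory infections (0: none, 1: one, 2: recurrent)"
    scores: {0: 0, 1: 1, 2: 2}
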