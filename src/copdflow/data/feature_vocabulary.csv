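key,definition
onset_midlife,Symptom onset in midlife
slowly_progressive_symptoms,Symptoms slowly progressive over years
smoking_history,History of tobacco smoking or exposure to other types of smoke
onset_early_life,Onset early in life (often in childhood)
symptoms_vary_day_to_day,Symptoms vary widely from day to day
symptoms_worse_night_morning,Symptoms worse at night or early morning
allergy_rhinitis_eczema,"Allergy, rhinitis and/or eczema also present"
family_history_asthma,Family history of asthma
obesity,Obesity coexistence
xray_dilated_heart,Chest X-ray shows dilated heart
pulmonary_edema,Chest X-ray shows pulmonary edema
volume_restriction,"Pulmonary function tests indicate volume restriction, not airflow limitation"
purulent_sputum_large_volume,Large volumes of purulent sputum
bacterial_infection_association,Commonly associated with bacterial infection
imaging_bronchial_dilatation,Chest radiograph/CT shows bronchial dilatation and bronchial wall thickening
onset_all_ages,Onset at all ages
xray_lung_infiltrate,Chest X-ray shows lung infiltrate
microbiological_confirmation,Microbiological confirmation available
high_local_tb_prevalence,High local prevalence of tuberculosis
onset_younger_nonsmoker,Onset at younger age in nonsmokers
history_ra_or_fume_exposure,History of rheumatoid arthritis or acute fume exposure
post_transplantation,Seen after lung or bone marrow transplantation
ct_expiratory_hypodense_areas,CT on expiration shows hypodense areas
asian_descent,Predominantly seen in patients of Asian descent
male_nonsmoker,Most patients are male and nonsmokers
chronic_sinusitis,Almost all cases involve chronic sinusitis
imaging_centrilobular_nodules,Chest X-ray and HRCT show diffuse small centrilobular nodular opacities and hyperinflation
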