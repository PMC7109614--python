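diagnosis,feature_key,source_text
COPD,onset_midlife,Onset in midlife
COPD,slowly_progressive_symptoms,Symptoms slowly progressive
COPD,smoking_history,History of tobacco smoking or exposure to other types of smoke
asthma,onset_early_life,Onset early in life (often in childhood)
asthma,symptoms_vary_day_to_day,Symptoms vary widely from day to day
asthma,symptoms_worse_night_morning,Symptoms worse at night/early morning
asthma,allergy_rhinitis_eczema,"Allergy, rhinitis, and/or eczema also present"
asthma,family_history_asthma,Family history of asthma
asthma,obesity,Obesity coexistence
congestive heart failure,xray_dilated_heart,"Chest X-ray shows dilated heart, pulmonary edema"
congestive heart failure,pulmonary_edema,"Chest X-ray shows dilated heart, pulmonary edema"
congestive heart failure,volume_restriction,"Pulmonary function tests indicate volume restriction, not airflow limitation"
bronchiectasis,purulent_sputum_large_volume,Large volumes of purulent sputum
bronchiectasis,bacterial_infection_association,Commonly associated with bacterial infection
bronchiectasis,imaging_bronchial_dilatation,"Chest radiograph/CT scans show bronchial dilatation, bronchial wall thickening"
tuberculosis,onset_all_ages,Onset at all ages
tuberculosis,xray_lung_infiltrate,Chest X-ray shows lung infiltrate
tuberculosis,microbiological_confirmation,Microbiological confirmation
tuberculosis,high_local_tb_prevalence,High local prevalence of tuberculosis
obliterative bronchiolitis,onset_younger_nonsmoker,"Onset at younger age, nonsmokers"
obliterative bronchiolitis,history_ra_or_fume_exposure,May have history of rheumatoid arthritis or acute fume exposure
obliterative bronchiolitis,post_transplantation,Seen after lung or bone marrow transplantation
obliterative bronchiolitis,ct_expiratory_hypodense_areas,CT on expiration shows hypodense areas
diffuse panbronchiolitis,asian_descent,Predominantly seen in patients of Asian descent
diffuse panbronchiolitis,male_nonsmoker,Most patients are male and nonsmokers
diffuse panbronchiolitis,chronic_sinusitis,Almost all cases involve chronic sinusitis
diffuse panbronchiolitis,imaging_centrilobular_nodules,Chest X-ray and HRCT show diffuse small centrilobular nodular opacities and hyperinflation
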