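# source: NHANES III spirometric reference equations (Hankinson, Odencrantz & Fedan 1999), adult rows, transcribed; replace via EngineConfig.equations_path
# ratio columns are FEV1/FVC in percent: pred = ratio_intercept + ratio_age*age; LLN = ratio_lln_intercept + ratio_age*age
# fev1 columns in liters: pred = fev1_intercept + fev1_age*age + fev1_age2*age^2 + fev1_ht2*height_cm^2
sex,group,age_min,age_max,height_min_cm,height_max_cm,ratio_intercept,ratio_age,ratio_lln_intercept,ratio_see,fev1_intercept,fev1_age,fev1_age2,fev1_ht2
male,caucasian,18,90,140,200,88.066,-0.2066,78.388,,0.5536,-0.01303,-0.000172,0.00014098
female,caucasian,18,90,140,200,90.809,-0.2125,81.015,,0.4333,-0.00361,-0.000194,0.00011496
male,african_american,18,90,140,200,89.239,-0.1828,78.822,,0.3411,-0.02309,0,0.00013194
female,african_american,18,90,140,200,91.655,-0.2039,80.978,,0.3433,-0.01283,-0.000097,0.00013497
male,mexican_american,18,90,140,200,90.024,-0.2186,80.925,,0.6306,-0.02928,0,0.00015104
female,mexican_american,18,90,140,200,92.36,-0.2248,83.044,,0.4529,-0.01178,-0.000113,0.00012154
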