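# source: BODE component cut-points (Celli et al. 2004); BODEx (Soler-Cataluna et al. 2009), transcribed; band convention: value v scores `points` for the unique row with min < v <= max (blank = unbounded)
index,component,min,max,points
bode,bmi,21,,0
bode,bmi,,21,1
bode,fev1_pct_pred,64,,0
bode,fev1_pct_pred,49,64,1
bode,fev1_pct_pred,35,49,2
bode,fev1_pct_pred,,35,3
bode,mmrc,,1,0
bode,mmrc,1,2,1
bode,mmrc,2,3,2
bode,mmrc,3,4,3
bode,six_mwd_m,349,,0
bode,six_mwd_m,249,349,1
bode,six_mwd_m,149,249,2
bode,six_mwd_m,,149,3
bodex,bmi,21,,0
bodex,bmi,,21,1
bodex,fev1_pct_pred,64,,0
bodex,fev1_pct_pred,49,64,1
bodex,fev1_pct_pred,35,49,2
bodex,fev1_pct_pred,,35,3
bodex,mmrc,,1,0
bodex,mmrc,1,2,1
bodex,mmrc,2,3,2
bodex,mmrc,3,4,3
bodex,exacerbations,,0,0
bodex,exacerbations,0,2,1
bodex,exacerbations,2,,2
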