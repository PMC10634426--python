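subject_id,arm,dose_mg,time_wk,obs_type,value,value_pred,auc,ins0,glu0,hba1c0,hgb0
EX0,placebo,0.0,0.0,basal_insulin,40.0,40.0,0.0,40.0,180.0,8.4,139.0
EX0,placebo,0.0,12.0,basal_insulin,40.0,40.0,0.0,40.0,180.0,8.4,139.0
EX0,placebo,0.0,24.0,basal_insulin,40.0,40.0,0.0,40.0,180.0,8.4,139.0
EX0,placebo,0.0,0.0,cgm_glucose,180.0,180.0,0.0,40.0,180.0,8.4,139.0
EX0,placebo,0.0,12.0,cgm_glucose,183.24,183.24,0.0,40.0,180.0,8.4,139.0
EX0,placebo,0.0,24.0,cgm_glucose,186.48000000000002,186.48000000000002,0.0,40.0,180.0,8.4,139.0
EX0,placebo,0.0,0.0,hba1c,8.4,8.4,0.0,40.0,180.0,8.4,139.0
EX0,placebo,0.0,12.0,hba1c,8.424948,8.424948,0.0,40.0,180.0,8.4,139.0
EX0,placebo,0.0,24.0,hba1c,8.449896,8.449896,0.0,40.0,180.0,8.4,139.0
EX1,5mg,5.0,0.0,basal_insulin,40.0,40.0,294.5,40.0,180.0,8.4,139.0
EX1,5mg,5.0,12.0,basal_insulin,36.674173417341734,36.674173417341734,294.5,40.0,180.0,8.4,139.0
EX1,5mg,5.0,24.0,basal_insulin,36.674173417341734,36.674173417341734,294.5,40.0,180.0,8.4,139.0
EX1,5mg,5.0,0.0,cgm_glucose,180.0,180.0,294.5,40.0,180.0,8.4,139.0
EX1,5mg,5.0,12.0,cgm_glucose,161.81696271340084,161.81696271340084,294.5,40.0,180.0,8.4,139.0
EX1,5mg,5.0,24.0,cgm_glucose,164.6781663763097,164.6781663763097,294.5,40.0,180.0,8.4,139.0
EX1,5mg,5.0,0.0,hba1c,8.4,8.4,294.5,40.0,180.0,8.4,139.0
EX1,5mg,5.0,12.0,hba1c,7.977008903541361,7.977008903541361,294.5,40.0,180.0,8.4,139.0
EX1,5mg,5.0,24.0,hba1c,7.998285395350985,7.998285395350985,294.5,40.0,180.0,8.4,139.0
EX2,10mg,10.0,0.0,basal_insulin,40.0,40.0,594.3,40.0,180.0,8.4,139.0
EX2,10mg,10.0,12.0,basal_insulin,36.46667951350497,36.46667951350497,594.3,40.0,180.0,8.4,139.0
EX2,10mg,10.0,24.0,basal_insulin,36.46667951350497,36.46667951350497,594.3,40.0,180.0,8.4,139.0
EX2,10mg,10.0,0.0,cgm_glucose,180.0,180.0,594.3,40.0,180.0,8.4,139.0
EX2,10mg,10.0,12.0,cgm_glucose,159.54507344221918,159.54507344221918,594.3,40.0,180.0,8.4,139.0
EX2,10mg,10.0,24.0,cgm_glucose,162.36610617498928,162.36610617498928,594.3,40.0,180.0,8.4,139.0
EX2,10mg,10.0,0.0,hba1c,8.4,8.4,594.3,40.0,180.0,8.4,139.0
EX2,10mg,10.0,12.0,hba1c,7.930833889059796,7.930833889059796,594.3,40.0,180.0,8.4,139.0
EX2,10mg,10.0,24.0,hba1c,7.951734496245307,7.951734496245307,594.3,40.0,180.0,8.4,139.0
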