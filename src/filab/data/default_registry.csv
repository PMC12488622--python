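name,kind,reference_low,reference_high,abnormal_categories,window_low_h,window_high_h,aggregation
hemoglobin,numeric_lab,12.0,16.0,,-6,24,first_in_window
wbc,numeric_lab,4.0,11.0,,-6,24,first_in_window
platelets,numeric_lab,150,400,,-6,24,first_in_window
alt,numeric_lab,7,56,,-6,24,first_in_window
alkaline_phosphatase,numeric_lab,44,147,,-6,24,first_in_window
total_bilirubin,numeric_lab,0.1,1.2,,-6,24,first_in_window
albumin,numeric_lab,3.5,5.0,,-6,24,first_in_window
ldh,numeric_lab,140,280,,-6,24,first_in_window
creatinine,numeric_lab,0.6,1.2,,-6,24,first_in_window
bun,numeric_lab,7,20,,-6,24,first_in_window
glucose,numeric_lab,70,110,,-6,24,first_in_window
sodium,numeric_lab,135,145,,-6,24,first_in_window
potassium,numeric_lab,3.5,5.0,,-6,24,first_in_window
calcium,numeric_lab,8.5,10.5,,-6,24,first_in_window
phosphate,numeric_lab,2.5,4.5,,-6,24,first_in_window
fibrinogen,numeric_lab,200,400,,-6,24,first_in_window
troponin_t,numeric_lab,0.0,0.01,,-6,24,first_in_window
pt,numeric_lab,11.0,13.5,,-6,24,first_in_window
inr,numeric_lab,0.8,1.2,,-6,24,first_in_window
aptt,numeric_lab,25,35,,-6,24,first_in_window
ph_arterial,numeric_lab,7.35,7.45,,-6,24,first_in_window
pao2,numeric_lab,75,100,,-6,24,first_in_window
paco2,numeric_lab,35,45,,-6,24,first_in_window
lactate,numeric_lab,0.5,2.0,,-6,24,first_in_window
urine_leukocytes,categorical_lab,,,trace;1+;2+;3+;positive,-6,24,first_in_window
urine_erythrocytes,categorical_lab,,,trace;1+;2+;3+;positive,-6,24,first_in_window
urine_protein,categorical_lab,,,trace;1+;2+;3+;positive,-6,24,first_in_window
urine_glucose,categorical_lab,,,trace;1+;2+;3+;positive,-6,24,first_in_window
urine_ketones,categorical_lab,,,trace;1+;2+;3+;positive,-6,24,first_in_window
urine_bilirubin,categorical_lab,,,trace;1+;2+;3+;positive,-6,24,first_in_window
sbp,vital_sign,90,140,,0,24,mean_in_window
dbp,vital_sign,60,90,,0,24,mean_in_window
heart_rate,vital_sign,60,100,,0,24,mean_in_window
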