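# Per-group prevalence (%) of the 30 chronic conditions across the ten patient
# groups of a large Scottish hospital multimorbidity cohort (11,389 multimorbid
# inpatients), used as the default condition profiles of the synthetic episode
# generator. overall_n / overall_pct are counts and prevalence over the whole
# multimorbid cohort; g1..g10 are percentages within each patient group.
condition,overall_n,overall_pct,g1,g2,g3,g4,g5,g6,g7,g8,g9,g10
Alcohol misuse,1155,10.1,6.9,6.0,75.4,3.4,4.1,2.0,0.9,3.2,3.4,1.8
Asthma,2074,18.2,4.7,68.9,20.5,12.2,11.3,20.6,8.6,9.5,14.1,17.1
Atrial fibrillation and flutter,2262,19.9,59.0,5.4,0.4,17.8,0.0,0.0,1.7,71.2,0.0,0.0
"Cancer, lymphoma",179,1.6,1.9,1.8,0.8,1.6,1.6,2.0,1.2,1.9,1.1,2.0
"Cancer, metastatic",635,5.6,2.3,0.7,0.5,1.7,2.7,0.7,71.7,0.9,1.7,0.4
"Cancer, non-metastatic (breast, cervical, colorectal, lung, prostate)",1291,11.3,10.5,5.7,3.7,4.8,8.0,2.2,92.0,4.3,5.9,2.8
Chronic heart failure,1470,12.9,11.7,5.7,3.9,17.4,6.7,5.5,2.1,84.6,8.7,4.9
Chronic kidney disease,2959,26.0,8.2,5.2,1.2,100.0,100.0,0.0,4.0,53.2,0.0,0.0
Chronic pain,1937,17.0,6.5,8.4,15.7,12.8,16.8,100.0,10.2,8.1,13.1,0.0
Chronic pulmonary disease (excludes asthma),2115,18.6,8.6,68.4,13.0,15.0,10.9,12.1,12.5,25.8,10.3,14.8
Chronic viral hepatitis B,16,0.1,0.2,0.0,0.5,0.0,0.1,0.2,0.0,0.0,0.1,0.0
Cirrhosis (and hepatic decompensation),383,3.4,2.4,2.7,12.1,3.9,2.6,0.8,3.2,2.4,2.9,2.0
Dementia,586,5.1,8.6,2.8,3.7,4.4,6.1,4.4,0.6,5.9,3.2,6.9
Depression,786,6.9,3.1,3.9,54.6,3.5,3.9,1.4,0.5,1.6,1.5,2.4
Diabetes,3071,27.0,11.0,5.5,15.1,100.0,0.0,0.0,3.2,8.9,100.0,0.0
Epilepsy,432,3.8,4.0,5.2,9.9,1.8,3.1,2.9,2.9,1.3,1.9,5.5
Hypertension,6430,56.5,77.5,58.1,6.3,72.2,64.7,53.7,9.9,14.7,71.4,60.8
Hypothyroidism,1647,14.5,7.7,5.5,9.6,12.0,14.7,14.9,7.8,10.2,13.8,100.0
Inflammatory bowel disease,347,3.0,4.1,4.0,1.5,1.9,3.5,3.7,2.9,1.3,1.9,3.9
Irritable bowel syndrome,170,1.5,1.5,2.2,2.4,0.6,0.9,3.6,0.6,0.4,0.9,2.0
Multiple sclerosis,128,1.1,1.6,0.9,0.9,0.6,1.1,1.2,0.9,0.1,1.5,1.0
Myocardial infarction,881,7.7,10.0,6.5,2.6,11.7,5.5,4.3,2.1,21.3,6.8,5.3
Parkinson's disease,188,1.7,2.7,0.9,1.4,0.7,1.6,2.3,0.5,1.9,1.4,1.0
Peptic ulcer disease (excluding bleeding),214,1.9,2.4,1.7,3.2,1.1,1.5,2.2,0.8,1.6,1.7,1.2
Peripheral vascular disease,27,0.2,0.2,0.3,0.0,0.3,0.3,0.1,0.0,0.3,0.3,0.4
Psoriasis,83,0.7,0.5,0.5,1.2,0.5,1.1,1.3,0.5,0.3,0.7,1.2
Rheumatoid arthritis,579,5.1,5.5,6.3,1.6,4.0,7.3,8.6,3.2,4.0,3.0,6.7
Schizophrenia,89,0.8,0.4,1.0,4.0,0.2,0.6,0.6,0.3,0.1,0.4,0.6
Severe constipation,1168,10.3,11.2,10.9,11.0,9.3,10.6,12.2,13.3,7.2,6.8,11.0
Stroke or transient ischaemic attack,764,6.7,12.6,5.3,4.5,5.7,5.4,4.1,2.1,6.3,5.5,3.9
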