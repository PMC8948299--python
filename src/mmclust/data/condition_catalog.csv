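# Default chronic-condition catalog: 30 conditions flagged from ICD-10 codes by
# leading-prefix match (Tonelli-style administrative-data multimorbidity measure;
# implementer-curated approximation, override with your own file if you hold the
# validated code list).
# Format: condition,icd10_prefix (one prefix per row, uppercase, dot-free).
condition,icd10_prefix
Alcohol misuse,F10
Alcohol misuse,G621
Alcohol misuse,I426
Asthma,J45
Asthma,J46
Atrial fibrillation and flutter,I48
"Cancer, lymphoma",C81
"Cancer, lymphoma",C82
"Cancer, lymphoma",C83
"Cancer, lymphoma",C84
"Cancer, lymphoma",C85
"Cancer, metastatic",C77
"Cancer, metastatic",C78
"Cancer, metastatic",C79
"Cancer, metastatic",C80
"Cancer, non-metastatic (breast, cervical, colorectal, lung, prostate)",C18
"Cancer, non-metastatic (breast, cervical, colorectal, lung, prostate)",C19
"Cancer, non-metastatic (breast, cervical, colorectal, lung, prostate)",C20
"Cancer, non-metastatic (breast, cervical, colorectal, lung, prostate)",C34
"Cancer, non-metastatic (breast, cervical, colorectal, lung, prostate)",C50
"Cancer, non-metastatic (breast, cervical, colorectal, lung, prostate)",C53
"Cancer, non-metastatic (breast, cervical, colorectal, lung, prostate)",C61
Chronic heart failure,I50
Chronic kidney disease,N03
Chronic kidney disease,N05
Chronic kidney disease,N18
Chronic pain,M54
Chronic pain,R52
Chronic pulmonary disease (excludes asthma),J40
Chronic pulmonary disease (excludes asthma),J41
Chronic pulmonary disease (excludes asthma),J42
Chronic pulmonary disease (excludes asthma),J43
Chronic pulmonary disease (excludes asthma),J44
Chronic pulmonary disease (excludes asthma),J47
Chronic viral hepatitis B,B181
Cirrhosis (and hepatic decompensation),I85
Cirrhosis (and hepatic decompensation),K70
Cirrhosis (and hepatic decompensation),K72
Cirrhosis (and hepatic decompensation),K74
Dementia,F00
Dementia,F01
Dementia,F02
Dementia,F03
Dementia,G30
Depression,F32
Depression,F33
Diabetes,E10
Diabetes,E11
Diabetes,E13
Diabetes,E14
Epilepsy,G40
Epilepsy,G41
Hypertension,I10
Hypertension,I15
Hypothyroidism,E02
Hypothyroidism,E03
Inflammatory bowel disease,K50
Inflammatory bowel disease,K51
Irritable bowel syndrome,K58
Multiple sclerosis,G35
Myocardial infarction,I21
Myocardial infarction,I22
Myocardial infarction,I252
Parkinson's disease,G20
Peptic ulcer disease (excluding bleeding),K25
Peptic ulcer disease (excluding bleeding),K26
Peptic ulcer disease (excluding bleeding),K27
Peptic ulcer disease (excluding bleeding),K28
Peripheral vascular disease,I70
Peripheral vascular disease,I73
Psoriasis,L40
Rheumatoid arthritis,M05
Rheumatoid arthritis,M06
Schizophrenia,F20
Schizophrenia,F25
Severe constipation,K590
Stroke or transient ischaemic attack,G45
Stroke or transient ischaemic attack,I60
Stroke or transient ischaemic attack,I61
Stroke or transient ischaemic attack,I63
Stroke or transient ischaemic attack,I64
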