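disease,year,prevalence_pct,source
Hypertension,2013,34.0,results_prose
Hypertension,2019,33.2,results_prose
Hypertension,2019,32.2,abstract
Hypertension,2019,32.3,region_panel
Hypertension,2019,32.4,age_panel
Lower back diseases,2013,20.4,results_prose
Lower back diseases,2013,20.5,region_panel
Lower back diseases,2019,19.5,results_prose
Cervical spine diseases,2013,13.1,results_prose
Cervical spine diseases,2019,13.1,results_prose
High Cholesterol,2013,13.9,results_prose
High Cholesterol,2019,12.6,results_prose
Coronary heart disease,2013,11.5,results_prose
Coronary heart disease,2019,10.7,results_prose
Arthrosis,2013,10.4,results_prose
Arthrosis,2019,9.1,results_prose
Diabetes mellitus,2013,8.4,results_prose
Diabetes mellitus,2019,8.5,results_prose
Allergies,2013,8.8,results_prose
Allergies,2019,8.0,results_prose
Depression,2013,6.8,results_prose
Depression,2019,5.8,results_prose
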