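disease,panel,stratum,year,prevalence_pct
Asthma,region,all,2013,3.7
Asthma,region,all,2019,3.6
Chronic lung diseases,region,all,2013,4.7
Chronic lung diseases,region,all,2019,3.7
Myocardial infarction,region,all,2013,2.8
Myocardial infarction,region,all,2019,2.0
Coronary heart disease,region,all,2013,11.6
Coronary heart disease,region,all,2019,9.8
Hypertension,region,all,2013,34.0
Hypertension,region,all,2019,32.3
Stroke,region,all,2013,2.2
Stroke,region,all,2019,1.4
Arthrosis,region,all,2013,10.4
Arthrosis,region,all,2019,7.8
Lower back diseases,region,all,2013,20.5
Lower back diseases,region,all,2019,18.4
Cervical spine diseases,region,all,2013,13.2
Cervical spine diseases,region,all,2019,13.0
Diabetes mellitus,region,all,2013,8.4
Diabetes mellitus,region,all,2019,8.8
Allergies,region,all,2013,8.8
Allergies,region,all,2019,7.0
Liver cirrhosis,region,all,2013,0.3
Liver cirrhosis,region,all,2019,0.3
Urinary track diseases,region,all,2013,4.6
Urinary track diseases,region,all,2019,3.9
Kidney diseases,region,all,2013,6.1
Kidney diseases,region,all,2019,4.2
Depression,region,all,2013,6.7
Depression,region,all,2019,4.8
High Cholesterol,region,all,2013,13.9
High Cholesterol,region,all,2019,11.2
Cancer,region,all,2013,1.6
Cancer,region,all,2019,2.0
Asthma,age,all,2013,3.6
Asthma,age,all,2019,3.6
Chronic lung diseases,age,all,2013,4.7
Chronic lung diseases,age,all,2019,3.7
Myocardial infarction,age,all,2013,2.7
Myocardial infarction,age,all,2019,2.0
Coronary heart disease,age,all,2013,11.6
Coronary heart disease,age,all,2019,9.7
Hypertension,age,all,2013,34.1
Hypertension,age,all,2019,32.4
Stroke,age,all,2013,2.3
Stroke,age,all,2019,1.5
Arthrosis,age,all,2013,10.5
Arthrosis,age,all,2019,7.7
Lower back diseases,age,all,2013,20.5
Lower back diseases,age,all,2019,18.5
Cervical spine diseases,age,all,2013,13.2
Cervical spine diseases,age,all,2019,13.1
Diabetes mellitus,age,all,2013,8.6
Diabetes mellitus,age,all,2019,8.6
Allergies,age,all,2013,8.8
Allergies,age,all,2019,7.0
Liver cirrhosis,age,all,2013,0.2
Liver cirrhosis,age,all,2019,0.3
Urinary track diseases,age,all,2013,4.5
Urinary track diseases,age,all,2019,3.8
Kidney diseases,age,all,2013,6.1
Kidney diseases,age,all,2019,4.2
Depression,age,all,2013,6.8
Depression,age,all,2019,4.7
High Cholesterol,age,all,2013,13.9
High Cholesterol,age,all,2019,11.4
Cancer,age,all,2013,1.5
Cancer,age,all,2019,2.0
Asthma,gender,male,pooled,1.7
Asthma,gender,female,pooled,2.1
Chronic lung diseases,gender,male,pooled,1.8
Chronic lung diseases,gender,female,pooled,2.4
Myocardial infarction,gender,male,pooled,1.5
Myocardial infarction,gender,female,pooled,0.9
Coronary heart disease,gender,male,pooled,4.3
Coronary heart disease,gender,female,pooled,6.4
Hypertension,gender,male,pooled,13.9
Hypertension,gender,female,pooled,19.3
Stroke,gender,male,pooled,0.9
Stroke,gender,female,pooled,0.9
Arthrosis,gender,male,pooled,2.6
Arthrosis,gender,female,pooled,6.5
Lower back diseases,gender,male,pooled,7.3
Lower back diseases,gender,female,pooled,12.2
Cervical spine diseases,gender,male,pooled,4.1
Cervical spine diseases,gender,female,pooled,9.0
Diabetes mellitus,gender,male,pooled,3.9
Diabetes mellitus,gender,female,pooled,4.7
Allergies,gender,male,pooled,2.8
Allergies,gender,female,pooled,5.2
Liver cirrhosis,gender,male,pooled,0.2
Liver cirrhosis,gender,female,pooled,0.2
Urinary track diseases,gender,male,pooled,2.1
Urinary track diseases,gender,female,pooled,2.2
Kidney diseases,gender,male,pooled,2.0
Kidney diseases,gender,female,pooled,3.1
Depression,gender,male,pooled,1.9
Depression,gender,female,pooled,3.8
High Cholesterol,gender,male,pooled,4.8
High Cholesterol,gender,female,pooled,7.9
Cancer,gender,male,pooled,0.6
Cancer,gender,female,pooled,1.1
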