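variable,level,n_patients,pct_total,n_metastasis,pct_metastasis
sex,female,139,36.7,29,20.9
sex,male,240,63.3,52,21.7
age_group,<=60,157,41.4,41,26.1
age_group,60-70,154,40.6,29,18.8
age_group,>70,68,17.9,11,16.2
familial_risk,low,196,51.7,34,17.3
familial_risk,intermediate/high,183,48.3,47,25.7
treatment_5fu,5-FU,214,56.5,59,27.6
treatment_5fu,other/none,159,42.0,17,10.7
treatment_5fu,unknown,6,1.6,5,83.3
stage,I,81,21.4,8,9.9
stage,II,158,41.7,30,19.0
stage,III,140,36.9,43,30.7
location,colon,233,61.5,41,17.6
location,rectum,146,38.5,40,27.4
histology,non-mucinous,343,90.5,75,21.9
histology,mucinous,36,9.5,6,16.7
vascular_invasion,absence,242,63.9,45,18.6
vascular_invasion,presence,111,29.3,30,27.0
vascular_invasion,unknown,26,6.9,6,23.1
lymphatic_invasion,absence,237,62.5,44,18.6
lymphatic_invasion,presence,116,30.6,31,26.7
lymphatic_invasion,unknown,26,6.9,6,23.1
braf_v600e,absence,333,87.9,72,21.6
braf_v600e,presence,19,5.0,8,42.1
braf_v600e,unknown,27,7.1,1,3.7
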