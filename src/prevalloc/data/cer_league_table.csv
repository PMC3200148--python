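short_name,program_code,age_label,population,average_cer,title
S1,S,20-44,general,1400,Minimal cessation counseling by GP
Sd1,Sd,20-44,diabetes,1500,Minimal cessation counseling by GP
Sd2,Sd,45-64,diabetes,2700,Minimal cessation counseling by GP
S2,S,45-64,general,2900,Minimal cessation counseling by GP
HL1,HL,20-44,general,3000,Hartslag Limburg
HL2,HL,45-64,general,5400,Hartslag Limburg
LA1,LA,20-44,diabetes,5800,LookAHEAD
XP1,XP,20-44,diabetes,5900,X-PERT
ISd1,ISd,20-44,diabetes,6400,Intensive smoking cessation counseling plus pharmacotherapy
IS1,IS,20-44,general,6700,Intensive smoking cessation counseling plus pharmacotherapy
BPd1,BPd,20-44,diabetes,6800,Medication to reduce blood pressure for persons with SBP > 140
XP2,XP,45-64,diabetes,7400,X-PERT
BPd2,BPd,45-64,diabetes,7800,Medication to reduce blood pressure for persons with SBP > 140
Sd3,Sd,65+,diabetes,8000,Minimal cessation counseling by GP
IS2,IS,45-64,general,8600,Intensive smoking cessation counseling plus pharmacotherapy
ISd2,ISd,45-64,diabetes,9200,Intensive smoking cessation counseling plus pharmacotherapy
Std2,Std,45-64,diabetes,9800,Statins for all diabetes patients
LA2,LA,45-64,diabetes,10100,LookAHEAD
S3,S,65+,general,10500,Minimal cessation counseling by GP
BP2,BP,45-64,general,10900,Medication to reduce blood pressure for persons with SBP > 140
Std1,Std,20-44,diabetes,11000,Statins for all diabetes patients
BP1,BP,20-44,general,11200,Medication to reduce blood pressure for persons with SBP > 140
BPd3,BPd,65+,diabetes,12900,Medication to reduce blood pressure for persons with SBP > 140
HL3,HL,65+,general,16100,Hartslag Limburg
BP3,BP,65+,general,16600,Medication to reduce blood pressure for persons with SBP > 140
Std3,Std,65+,diabetes,16600,Statins for all diabetes patients
St1,St,20-44,general,18100,Statins for persons with total cholesterol > 6.5
St2,St,45-64,general,18500,Statins for persons with total cholesterol > 6.5
XP3,XP,65+,diabetes,19700,X-PERT
SL1,SL,20-44,general,19900,SLIM
SL2,SL,45-64,general,27300,SLIM
St3,St,65+,general,28100,Statins for persons with total cholesterol > 6.5
ISd3,ISd,65+,diabetes,32300,Intensive smoking cessation counseling plus pharmacotherapy
LA3,LA,65+,diabetes,33200,LookAHEAD
IS3,IS,65+,general,35500,Intensive smoking cessation counseling plus pharmacotherapy
SL3,SL,65+,general,59600,SLIM
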