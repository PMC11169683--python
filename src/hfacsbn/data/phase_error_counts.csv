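phase,error_type,count
assessment of patient,ICD implantation is not considered,3
simulation,wrong treatment field size,1
simulation,machine breakdown,1
delineation,wrong definition,9
delineation,wrong CT image used,2
delineation,wrong registration,1
treatment planning,wrong data transfer or setting,17
treatment planning,treatment history not considered,4
treatment planning,organ at risk dose out of limits,4
treatment planning,wrong structure copy,2
planning approval,the wrong treatment plan passed,4
patient exchange,patient ID not verified,3
wrong patient set-up,markers not correctly identified or wrong verification,15
wrong delivery,repeated irradiation or missed irradiation,12
no attention to the treatment room,collision of gantry and couch,2
patient status was not observed,patient has difficulty breathing,1
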