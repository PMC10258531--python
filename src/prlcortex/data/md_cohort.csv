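participant,diagnosis,onset_group,sex,age,age_onset,disease_duration,better_eye,acuity_logmar,prl_ecc_deg,prl_bcea63_deg2
MDP004,Age-related,LO,F,73,56,17,right,0.2,4.85,7.2
MDP006,Age-related,LO,F,50,46,4,left,0.9,4.30,6.8
MDP008,Age-related,LO,F,70,50,20,left,0.9,12.9,54.5
MDP014,Age-related,LO,M,68,34,34,left,1.3,10.13,10.1
MDP016,Age-related,LO,M,55,42,13,right,0.2,17.1,9.3
MDP022,Age-related,LO,F,83,70,13,right,0.7,6.98,18.8
MDP047,Age-related,LO,M,77,71,6,right,0.2,5.14,11.4
MDP050,Age-related,LO,M,83,73,10,left,0.8,7.79,12.2
MDP065,Age-related,LO,F,61,38,23,left,0.9,12.56,27.4
MDP117,Age-related,LO,M,88,82,6,left,0.2,5.19,9.7
MDP123,Age-related,LO,F,70,66,4,right,1.0,6.15,5.5
MDP126,Age-related,LO,M,83,65,18,right,0.6,3.33,2.7
MDP142,Age-related,LO,M,75,67,8,right,1.0,13.96,12.7
MDP174,Age-related,LO,F,57,47,10,left,1.3,9.46,84.4
MDP005,Juvenile-onset,EO,M,22,15,7,right,0.8,10.88,9.7
MDP021,Stargardt,EO,M,27,14,13,left,1.0,9.16,36.3
MDP023,Stargardt,EO,F,35,20,16,right,1.3,8.19,12.0
MDP027,Age-related,EO,F,68,21,47,left,1.0,19.62,22.1
MDP043,Age-related,EO,M,65,18,47,left,1.3,12.83,59.9
MDP122,Juvenile-onset,EO,F,70,19,51,left,1.3,12.37,16.9
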