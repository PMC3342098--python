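algorithm,diagnosis,n_cases,fp,tp,fn,tn,fit
chuk,tb_smear_positive,43,1,42,1,140,43
chuk,miliary_tb,18,0,18,0,166,18
chuk,pleural_tb,25,0,24,1,159,25
chuk,pcp,39,0,39,0,145,39
chuk,lobar_pneumonia,21,3,20,1,160,21
chuk,atypical_pneumonia,18,1,17,1,165,18
chuk,empyema,3,0,3,0,181,3
chuk,kaposi_sarcoma,7,0,7,0,177,7
chuk,lung_abscess,3,0,0,3,181,2
chuk,cavitary_tb,2,1,2,0,181,2
chuk,mediastinal_adp_tb,3,1,2,1,180,3
chuk,pericardial_tb,2,0,2,0,182,2
msf,tb_smear_positive,43,0,43,0,141,43
msf,miliary_tb,18,0,18,0,166,18
msf,pleural_tb,25,0,25,0,159,25
msf,pcp,39,0,39,0,145,39
msf,lobar_pneumonia,21,0,1,20,163,21
msf,atypical_pneumonia,18,20,18,0,146,18
msf,empyema,3,0,3,0,181,3
msf,kaposi_sarcoma,7,0,7,0,177,7
msf,lung_abscess,3,1,3,0,180,3
msf,cavitary_tb,2,0,0,2,182,1
msf,mediastinal_adp_tb,3,0,3,0,181,3
msf,pericardial_tb,2,0,2,0,182,2
who,tb_smear_positive,43,0,43,0,141,43
who,miliary_tb,18,0,18,0,166,18
who,pleural_tb,25,0,3,22,159,24
who,pcp,39,0,39,0,145,39
who,lobar_pneumonia,21,0,1,20,163,21
who,atypical_pneumonia,18,20,18,0,146,18
who,empyema,3,0,0,3,181,0
who,kaposi_sarcoma,7,0,7,0,177,7
who,lung_abscess,3,0,0,3,181,0
who,cavitary_tb,2,0,0,2,182,0
who,mediastinal_adp_tb,3,0,0,3,181,0
who,pericardial_tb,2,0,0,2,182,1
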