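diagnosis,chuk_days,msf_days,actual_chuk_days,minimal_days
tb_smear_positive,3.14,2.91,2.3,3
miliary_tb,1,3,1.6,1
pleural_tb,2.28,4,3.4,2
pcp,1.03,3.45,0,1
lobar_pneumonia,1.09,3.09,0.8,1
atypical_pneumonia,1.67,4.83,0.2,1
empyema,1.67,3.67,6.7,2
kaposi_sarcoma,1.57,3.14,1.6,1
lung_abscess,1,3,1,1
cavitary_tb,1.5,3,0,1
mediastinal_adp_tb,4.33,6,3,1
pericardial_tb,2,4,0,1
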