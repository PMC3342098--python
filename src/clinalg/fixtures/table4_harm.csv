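diagnosis,w_omission,w_commission
tb_smear_positive,9,5
miliary_tb,8.5,5
pleural_tb,7.5,4.5
pcp,8,3
lobar_pneumonia,8,3
atypical_pneumonia,7,3
empyema,8,4
kaposi_sarcoma,7,7.5
lung_abscess,8,4
cavitary_tb,8,5
mediastinal_adp_tb,7.5,5
pericardial_tb,8,5
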