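test_id,turnaround_days
chest_xray,1
sputum_smear,2
pleural_tap,1
antibiotic_trial,2
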