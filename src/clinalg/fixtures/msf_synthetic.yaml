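# Synthetic reconstruction of a published smear-first chronic-cough flowchart
# for HIV-positive patients (tertiary level).  The published figure is not
# machine-readable; this encoding is a best-effort stand-in, NOT a
# transcription.
algorithm_id: msf
name: Smear-first chronic-cough algorithm (synthetic reconstruction)
entry: entry
nodes:
  - {id: entry, kind: clinical_state, label: "HIV-positive adult, cough > 3 weeks"}
  - {id: do_smear, kind: other_action, label: "sputum smear x3", test: sputum_smear, delay_days: 2}
  - {id: d_smear, kind: decision, label: "smear positive?",
     predicate: {finding: smear_result, op: equals, value: positive}}
  - {id: do_xray_pos, kind: other_action, label: "chest X-ray", test: chest_xray, delay_days: 1}
  - {id: d_miliary_pos, kind: decision, label: "miliary pattern?",
     predicate: {finding: xray_pattern, op: equals, value: miliary}}
  - {id: dx_miliary, kind: diagnostic_action, label: "treat miliary TB", diagnosis: miliary_tb}
  - {id: d_cavity, kind: decision, label: "cavitary pattern?",
     predicate: {finding: xray_pattern, op: equals, value: cavity}}
  - {id: dx_cavitary, kind: diagnostic_action, label: "treat cavitary TB", diagnosis: cavitary_tb}
  - {id: dx_tb, kind: diagnostic_action, label: "treat smear-positive TB", diagnosis: tb_smear_positive}
  - {id: do_xray_neg, kind: other_action, label: "chest X-ray", test: chest_xray, delay_days: 1}
  - {id: d_effusion, kind: decision, label: "pleural effusion?",
     predicate: {finding: pleural_effusion, op: present}}
  - {id: do_tap, kind: other_action, label: "pleural tap", test: pleural_tap, delay_days: 1}
  - {id: d_purulent, kind: decision, label: "purulent tap?",
     predicate: {finding: tap_purulent, op: present}}
  - {id: dx_empyema, kind: diagnostic_action, label: "drain + antibiotics", diagnosis: empyema}
  - {id: dx_pleural, kind: diagnostic_action, label: "treat pleural TB", diagnosis: pleural_tb}
  - {id: d_pericardial, kind: decision, label: "pericardial effusion?",
     predicate: {finding: pericardial_effusion, op: present}}
  - {id: dx_pericardial, kind: diagnostic_action, label: "treat pericardial TB", diagnosis: pericardial_tb}
  - {id: d_kaposi, kind: decision, label: "mucocutaneous Kaposi lesions?",
     predicate: {finding: kaposi_lesions, op: present}}
  - {id: dx_kaposi, kind: diagnostic_action, label: "refer for Kaposi sarcoma", diagnosis: kaposi_sarcoma}
  - {id: d_adp, kind: decision, label: "mediastinal adenopathy?",
     predicate: {finding: mediastinal_adenopathy, op: present}}
  - {id: dx_adp, kind: diagnostic_action, label: "treat mediastinal ADP TB", diagnosis: mediastinal_adp_tb}
  - {id: d_abscess, kind: decision, label: "cavity with air-fluid level?",
     predicate: {finding: cavity_air_fluid_level, op: present}}
  - {id: dx_abscess, kind: diagnostic_action, label: "treat lung abscess", diagnosis: lung_abscess}
  - {id: d_interstitial, kind: decision, label: "diffuse interstitial pattern?",
     predicate: {finding: xray_pattern, op: equals, value: interstitial}}
  - {id: dx_pcp, kind: diagnostic_action, label: "treat pneumocystosis", diagnosis: pcp}
  - {id: d_consolidation, kind: decision, label: "lobar consolidation?",
     predicate: {finding: xray_pattern, op: equals, value: lobar}}
  - {id: dx_lobar, kind: diagnostic_action, label: "treat lobar pneumonia", diagnosis: lobar_pneumonia}
  - {id: dx_atypical, kind: diagnostic_action, label: "treat atypical pneumonia", diagnosis: atypical_pneumonia}
edges:
  - {from: entry, to: do_smear, branch: next}
  - {from: do_smear, to: d_smear, branch: next}
  - {from: d_smear, to: do_xray_pos, branch: yes}
  - {from: do_xray_pos, to: d_miliary_pos, branch: next}
  - {from: d_miliary_pos, to: dx_miliary, branch: yes}
  - {from: d_miliary_pos, to: d_cavity, branch: no}
  - {from: d_cavity, to: dx_cavitary, branch: yes}
  - {from: d_cavity, to: dx_tb, branch: no}
  - {from: d_smear, to: do_xray_neg, branch: no}
  - {from: do_xray_neg, to: d_effusion, branch: next}
  - {from: d_effusion, to: do_tap, branch: yes}
  - {from: do_tap, to: d_purulent, branch: next}
  - {from: d_purulent, to: dx_empyema, branch: yes}
  - {from: d_purulent, to: dx_pleural, branch: no}
  - {from: d_effusion, to: d_pericardial, branch: no}
  - {from: d_pericardial, to: dx_pericardial, branch: yes}
  - {from: d_pericardial, to: d_kaposi, branch: no}
  - {from: d_kaposi, to: dx_kaposi, branch: yes}
  - {from: d_kaposi, to: d_adp, branch: no}
  - {from: d_adp, to: dx_adp, branch: yes}
  - {from: d_adp, to: d_abscess, branch: no}
  - {from: d_abscess, to: dx_abscess, branch: yes}
  - {from: d_abscess, to: d_interstitial, branch: no}
  - {from: d_interstitial, to: dx_pcp, branch: yes}
  - {from: d_interstitial, to: d_consolidation, branch: no}
  - {from: d_consolidation, to: dx_lobar, branch: yes}
  - {from: d_consolidation, to: dx_atypical, branch: no}
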