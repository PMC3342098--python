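# Synthetic reconstruction of a short, sparsely specified chronic-cough
# flowchart of the early-1990s global-guideline style: smear first, a single
# X-ray reading, a narrower diagnosis spectrum (no empyema/abscess/cavitary/
# ADP/pericardial endpoints).  Best-effort stand-in, NOT a transcription.
algorithm_id: who
name: Global chronic-cough algorithm (synthetic reconstruction)
entry: entry
nodes:
  - {id: entry, kind: clinical_state, label: "HIV-positive adult, cough > 3 weeks"}
  - {id: do_smear, kind: other_action, label: "sputum smear x3", test: sputum_smear, delay_days: 2}
  - {id: d_smear, kind: decision, label: "smear positive?",
     predicate: {finding: smear_result, op: equals, value: positive}}
  - {id: dx_tb, kind: diagnostic_action, label: "treat smear-positive TB", diagnosis: tb_smear_positive}
  - {id: do_xray, kind: other_action, label: "chest X-ray", test: chest_xray, delay_days: 1}
  - {id: d_miliary, kind: decision, label: "miliary pattern?",
     predicate: {finding: xray_pattern, op: equals, value: miliary}}
  - {id: dx_miliary, kind: diagnostic_action, label: "treat miliary TB", diagnosis: miliary_tb}
  - {id: d_effusion, kind: decision, label: "pleural effusion?",
     predicate: {finding: pleural_effusion, op: present}}
  - {id: dx_pleural, kind: diagnostic_action, label: "treat pleural TB", diagnosis: pleural_tb}
  - {id: d_kaposi, kind: decision, label: "mucocutaneous Kaposi lesions?",
     predicate: {finding: kaposi_lesions, op: present}}
  - {id: dx_kaposi, kind: diagnostic_action, label: "refer for Kaposi sarcoma", diagnosis: kaposi_sarcoma}
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
  - {from: d_smear, to: dx_tb, branch: yes}
  - {from: d_smear, to: do_xray, branch: no}
  - {from: do_xray, to: d_miliary, branch: next}
  - {from: d_miliary, to: dx_miliary, branch: yes}
  - {from: d_miliary, to: d_effusion, branch: no}
  - {from: d_effusion, to: dx_pleural, branch: yes}
  - {from: d_effusion, to: d_kaposi, branch: no}
  - {from: d_kaposi, to: dx_kaposi, branch: yes}
  - {from: d_kaposi, to: d_interstitial, branch: no}
  - {from: d_interstitial, to: dx_pcp, branch: yes}
  - {from: d_interstitial, to: d_consolidation, branch: no}
  - {from: d_consolidation, to: dx_lobar, branch: yes}
  - {from: d_consolidation, to: dx_atypical, branch: no}
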