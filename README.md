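# clinalg

Virtual evaluation of serial dichotomous clinical algorithms.

Clinical guidelines are often published as flowcharts: a patient enters at a
clinical state (say, *HIV-positive adult with cough for more than three
weeks*), answers a chain of yes/no questions about findings and test
results, and exits at a management decision. Before deploying such an
algorithm — or choosing between competing ones — it can be "dry-run"
against a database of patients whose true diagnoses are known. `clinalg` is
a framework for exactly that: it encodes flowcharts declaratively, routes
(real or synthetic) patient cohorts through them, and scores each flowchart
for accuracy, speed, expected harm and structural complexity. It ships
worked fixtures for a three-way comparison of tertiary-level chronic-cough
algorithms in an HIV-positive hospital cohort (n = 201, 12 in-scope
diagnoses dominated by tuberculosis and pneumocystosis).

## What is computed

For each case (one patient–diagnosis pair; a patient with two diagnoses
contributes two cases) the engine simulates step-by-step management. A case
**fits** if it reaches a terminal action box; it stalls if a decision needs
an unrecorded finding or a loop repeats beyond its bound. Accounting per
case, with `d*` the true diagnosis and `d̂` the diagnosis reached:

- `d̂ = d*` → one true positive for `d*`;
- `d̂ ≠ d*` (some other diagnosis reached) → a false negative for `d*`
  **and** a false positive for `d̂`;
- no fit, or a non-diagnostic endpoint → a false negative for `d*` only.

From the per-diagnosis counts the framework reports:

- **Sensitivity** `100·ΣTP/(ΣTP+ΣFN)` over in-scope cases (restricted), or
  `100·ΣTP/N_enrolled` counting undiagnosed and rare-diagnosis patients in
  the denominator (inclusive).
- **Serial delay**: each box consumes its turnaround when entered
  (investigations assumed strictly sequential); per-diagnosis delays are
  averaged with or without case-count weighting.
- **Harm** = `Σ_d FP_d·w_commission(d) + Σ_d FN_d·w_omission(d)`, with
  per-diagnosis harm weights on a 0–10 scale elicited from clinicians.
- **CASA** structural complexity `2·n1Dx + 1·n2D0 + Σ(Lp)_i`, where `n1Dx`
  counts diagnostic boxes, `n2D0` all other boxes and each loop (an edge
  sending the clinician back to an earlier box) contributes a loop
  parameter.
- **CAPA** similarity of two algorithms on the same patients: each case's
  pathway is abstracted to (ordered tests, terminal decision) and scored
  identical (10), similar (8: same tests, different order) or different (0).

A synthetic-cohort generator completes the loop: finding archetypes are
*calibrated* from a flowchart by path-constraint back-propagation, so that a
noise-free archetype cohort is recovered perfectly, and a configurable
noise rate then produces the two realistic failure modes (stalls and
misroutes).

## Worked example

Score the three packaged flowchart reconstructions on the packaged
study-shaped synthetic cohort (201 patients, 202 diagnoses, 184 in-scope
cases):

```
$ clinalg compare \
    --algorithm src/clinalg/fixtures/chuk_synthetic.yaml \
    --algorithm src/clinalg/fixtures/msf_synthetic.yaml \
    --algorithm src/clinalg/fixtures/who_synthetic.yaml \
    --cohort src/clinalg/fixtures/table1_cohort_synthetic.csv \
    --harm src/clinalg/fixtures/table4_harm.csv
algorithm  n_cases  fit  fit_pct  sensitivity_pct  sensitivity_inclusive_pct  mean_delay_days  harm_commission  harm_omission  harm_total  casa_score
     chuk      184  184    100.0             99.5                       91.0             2.72              5.0            8.0        13.0        42.0
      who      171  171    100.0             99.4                       84.6             2.74              5.0            8.0        13.0        23.0
      msf      184  184    100.0             89.7                       82.1             3.15             59.0          161.0       220.0        40.0
CAPA chuk vs msf: aggregate 8 (identical 0% / similar 58% / different 42%; 7 cases not comparable)
CAPA chuk vs who: aggregate 0 (identical 0% / similar 34% / different 66%; 7 cases not comparable)
CAPA msf vs who: aggregate 0 (identical 49% / similar 0% / different 51%; 7 cases not comparable)
```

The cohort's findings are calibrated archetypes of the `chuk` flowchart, so
`chuk` misses only the second diagnosis of the one dual-diagnosis patient
(183/184 = 99.5%; a serial algorithm can follow only one pathway per
patient, so the other diagnosis is necessarily missed — harm 13 = one
omission at weight 8 plus one commission at weight 5). The smear-first
`msf` reconstruction misroutes some X-ray-defined diagnoses it orders
differently (89.7%), and the short `who` reconstruction covers only 7 of
the 12 diagnoses, so 18 additional cases fall out of scope (`n_cases`
171 here counts its in-scope cases). CAPA shows `chuk` and `msf` often use
the same tests in a different order (score 8), while the sparser `who`
pathway is mostly plain different (score 0).

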