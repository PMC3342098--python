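# Methods

## The evaluation model

A clinical algorithm is modelled as a rooted directed graph of typed boxes:
a clinical state (the entry), yes/no decision boxes, diagnostic action
boxes (the only kind carrying a diagnosis label) and other action boxes
(tests, trials, referrals). Branching is strictly dichotomous — every
decision box has exactly one yes-edge and one no-edge — and the logic is
serial: a patient follows exactly one pathway. Polychotomous questions must
be encoded as chained binary decisions. Loops (edges returning to an
earlier box, e.g. "no improvement → repeat the X-ray") are first-class:
they are detected from the entry-rooted depth-first ordering, and an
explicit `backward` flag in a document overrides detection, because
published figures mark loops graphically and an encoding should be able to
assert them.

Virtual application answers each decision from the patient's findings map.
The evaluation is three-valued: a finding can be true/false (or compared
against a reference value), or *unknown*. Unknown never defaults to a
branch — the walk stalls with a distinct no-fit status, because "fit" (the
fraction of patients who find a way through) is itself a reported outcome
and its complement must be well defined. The other stall statuses are a
loop bound exceeded (default 3 iterations, configurable; real re-testing
loops are clinically bounded but rarely specified) and a dead end, which
cannot occur in a validated flowchart but is kept as a status rather than
an exception so that batch runs never abort on one case.

### Error accounting

Each case contributes to per-diagnosis confusion counts by an asymmetric
rule: reaching the right diagnosis is a true positive; reaching a wrong
diagnosis is a false negative for the true condition *and* a false positive
for the wrongly assigned one; stalling, or ending at a non-diagnostic
action, is a false negative only. This makes TP+FN per diagnosis equal its
case count even when some cases never fit — which is exactly what the
packaged count tables exhibit (the least-fitting algorithm fits 171 of 184
cases yet its TP+FN totals 184). True negatives are completed by
conservation, `TN = N − TP − FP − FN`. Cases whose true diagnosis is a
sentinel (no final diagnosis, rare diagnosis) or outside the flowchart's
spectrum are excluded from the restricted analysis; the inclusive
sensitivity instead divides total true positives by all enrolled patients.

### Delay

Delay is theoretical-serial: every box consumes its `delay_days` on entry,
re-entered boxes consume it again, and the pathway delay is the sum until
fit or stall. Clinicians in practice parallelise (reading the X-ray while
sputa are incubating), so these numbers are an upper bound by design and
are interpreted comparatively, not absolutely. Cohort-level summaries
average per-diagnosis delays either weighted by case counts (the default,
which reproduces the published 1.86-day average for the locally tailored
algorithm) or unweighted across diagnoses. The published 3.46-day average
for the smear-first algorithm is reproduced by neither rule exactly
(case-weighted gives 3.48, unweighted 3.67); the framework reports the
computed value and leaves the discrepancy visible rather than fitting a
bespoke averaging rule.

### Harm

Harm weights are per-diagnosis intuitive scores on a 0–10 scale, elicited
from clinicians, for omission (missing the diagnosis) and commission
(wrongly assigning it); omission is weighted roughly twice as heavily on
average (8 vs 4.5). Harm is the error-weighted sum
`Σ FP_d·w_commission(d) + Σ FN_d·w_omission(d)`, split into commission and
omission components. One arithmetic note: the packaged count and weight
tables yield a total of 90 for the locally tailored algorithm (27 + 63),
while the study text prints 91 against its own printed split; the framework
always reports the computed sum.

### Nosology

CASA complexity is `2·n1Dx + 1·n2D0 + Σ(Lp)_i`. The box census is
unambiguous; the valuation of a loop parameter `Lp` is not fixed by the
source methodology, so it is a pluggable rule: `unit` (1 per backward edge,
the default — the most conservative reading) or `enclosed` (the number of
boxes the loop spans in depth-first order, which penalises long
re-evaluation loops). Both are reported by the CLI; neither is asserted as
ground truth.

CAPA abstracts each case's pathway to (ordered test identifiers, terminal
decision) and scores a pair of algorithms per case: identical (10) for the
same ordered tests and decision, similar (8) for the same test multiset in
a different order with the same decision, different (0) otherwise. The
published definition leaves "same decision but different test sets"
unclassified; it is scored 0 here, since the management differs. Cases
that fail to fit either algorithm cannot be abstracted and are excluded
(their count is reported). The single aggregate is the modal category
score, the simplest statistic consistent with reporting one number; the
full distribution is always emitted alongside. The same 10/8/0 scale
scores concordance between a traversal and an observed ward management,
comparing the observed treatment label with the terminal diagnosis.

## Synthetic cohorts

The generator emulates the study-shaped cohort: 201 patients, a disease
spectrum of 12 in-scope diagnoses plus 9 rare-diagnosis and 9 undiagnosed
sentinels, 82/119 male/female, six age bands over 16–74 years, ~39% crude
mortality (sampled but driving no scoring), and a dual-diagnosis rate of
1/183 mirroring the single dual-diagnosis patient. Default prevalences are
the spectrum counts normalised by 202 (the counts sum to one more than the
patient total precisely because of the dual-diagnosis patient).

Findings are conditionally independent given the (primary) diagnosis. No
per-diagnosis finding frequencies were ever published, so profiles are
*calibrated* from a flowchart: for each covered diagnosis, the predicate
outcomes along an entry→diagnosis path are back-propagated into a findings
archetype (a small constraint solver handles equality, set and interval
predicates and reports genuinely contradictory paths). Noise then replaces
each finding with probability ε/2 by unknown and with ε/2 by a
flipped/resampled value — producing, respectively, the stall and misroute
failure modes. Consequences used as test oracles: at ε = 0 with single
diagnoses the calibrating flowchart recovers 100% sensitivity and zero
harm, and mean sensitivity is non-increasing in ε (checked over
ε ∈ {0, 0.05, 0.15, 0.3}, 20 seeds each). A dual-diagnosis patient breaks
exact 100% recovery by construction — a serial flowchart follows one
pathway, so the second diagnosis is always missed — which is why the
exact-recovery checks set the dual rate to 0.

What the generator does **not** model: finding–finding correlation,
severity gradients, diagnostic uncertainty of the reference standard, and
outcome-dependent management. Passing the end-to-end checks therefore
demonstrates the pipeline's internal consistency, not performance on real
clinical data.

Generation is a pure function of the spec including its seed (one
`numpy` generator per cohort, no global state). The packaged 201-row
cohort fixture is a separate deterministic construction with *exact*
margins (not sampled), its findings being noise-free archetypes of the
locally tailored flowchart; it is synthetic — the study's raw records were
never published — and is labelled as such.

## Fixtures and reproduction scope

The per-diagnosis accuracy counts, serial delays and harm weights are
printed data and ship verbatim as CSV fixtures; every headline metric is
recomputed from them at run time by `replicate_study` (about a millisecond
of arithmetic). The three flowchart encodings are best-effort synthetic
reconstructions of figures that are not machine-readable; their CASA
scores are computed and reported but never asserted against the published
80/73/40, and the published clinician-concordance split (61/38/1) is not
asserted because per-patient observed management was never printed. Those
quantities are covered instead by property-based tests: round-trip
identity of the document format, confusion-count conservation on random
case streams, an exhaustive-enumeration traversal oracle, census and
insertion-monotonicity oracles for CASA (+1 per ordinary box, +2 per
diagnostic box), CAPA self-comparison, and the synthetic recovery
properties above.

## Numerical and reporting choices

Percentages are reported to 1 decimal, days and harm to 2; all comparisons
in tests are performed on exact values before rounding. Counting is
integer arithmetic throughout; the only floating-point quantities are
delays, weights and rates. Serialization is deterministic (entry-rooted
depth-first node order, ties by identifier; two serializations of the same
algorithm are byte-identical). Edge-case behaviour: an empty cohort
produces a zero-count report with undefined (NaN) sensitivity rather than
an error; a predicate applied to a non-numeric value where a threshold is
needed evaluates to unknown.

## Known limitations

- The engine models guideline-faithful management only; clinician deviation
  from the flowchart and treatment-response feedback (beyond encoded loop
  edges) are out of scope.
- Harm uses intuitive weights as given; calculated harm from
  treated/untreated outcome probabilities, and DALY/QALY conversion, are
  out of scope.
- Only point estimates are produced — no confidence intervals, matching the
  scope of the replicated tables.
- The flowchart reconstructions are structurally plausible stand-ins;
  conclusions that depend on box-level content of the original figures
  cannot be drawn from them.
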