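"""Synthetic patient cohorts with the statistical structure the analysis assumes.

The generator emulates a hospital cohort of HIV-positive adults with chronic
cough: a disease spectrum over twelve in-scope diagnoses plus rare-diagnosis
and no-diagnosis sentinels, per-diagnosis finding profiles, an age/sex
distribution, a small dual-diagnosis rate, and a configurable noise rate
that obscures (to unknown) or flips findings — the two mechanisms that
produce non-fits and misroutes downstream.

Finding profiles can be *calibrated* from a flowchart: for each covered
diagnosis, path-constraint back-propagation finds a findings archetype such
that a noise-free patient with that archetype traverses the flowchart to
exactly that diagnosis.  With zero noise, a calibrated cohort therefore
yields 100% sensitivity and zero harm on the calibrating flowchart — the
end-to-end consistency check for the whole pipeline.

Findings are conditionally independent given the diagnosis; real clinical
correlation structure is deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .cohort import NO_DIAGNOSIS, RARE_DIAGNOSIS, SENTINELS, PatientRecord
from .flowchart import UNKNOWN, ClinicalAlgorithm, NodeKind

__all__ = [
    "CohortSpec",
    "CalibrationError",
    "calibrate_profiles",
    "generate_cohort",
    "default_spec",
    "study_shaped_cohort",
    "load_cohort_spec",
    "TABLE1_DIAGNOSIS_COUNTS",
    "TABLE1_AGE_BANDS",
    "N_ENROLLED",
    "N_FEMALE",
    "N_MALE",
]


# Study-shaped margins: 201 enrolled patients, diagnosis spectrum, age bands,
# sex split and crude mortality of the cohort the framework emulates.
N_ENROLLED = 201
N_MALE, N_FEMALE = 82, 119
DEATH_RATE = 0.39

TABLE1_DIAGNOSIS_COUNTS: dict[str, int] = {
    "tb_smear_positive": 43,
    "pcp": 39,
    "pleural_tb": 25,
    "lobar_pneumonia": 21,
    "miliary_tb": 18,
    "atypical_pneumonia": 18,
    "kaposi_sarcoma": 7,
    "empyema": 3,
    "lung_abscess": 3,
    "mediastinal_adp_tb": 3,
    "cavitary_tb": 2,
    "pericardial_tb": 2,
    RARE_DIAGNOSIS: 9,
    NO_DIAGNOSIS: 9,
}  # counts sum to 202 over 201 patients: one patient carries two diagnoses

TABLE1_AGE_BANDS: dict[tuple[int, int], int] = {
    (16, 24): 22,
    (25, 34): 72,
    (35, 44): 69,
    (45, 54): 29,
    (55, 64): 8,
    (65, 74): 1,
}


class CalibrationError(ValueError):
    """No findings archetype can satisfy the path constraints."""


@dataclass
class CohortSpec:
    """Everything that parameterizes cohort generation, seed included.

    ``finding_profiles`` maps diagnosis -> finding -> (archetype value,
    probability the archetype value is expressed); findings absent from a
    profile take the baseline value.  ``noise_rate`` ε obscures a finding to
    unknown with probability ε/2 and flips/resamples it with ε/2.
    """

    n_patients: int
    prevalence: dict[str, float]
    finding_profiles: dict[str, dict[str, tuple[object, float]]]
    baseline_findings: dict[str, object] = field(default_factory=dict)
    noise_rate: float = 0.0
    multi_dx_rate: float = 1.0 / 183.0
    age_band_probs: dict[tuple[int, int], float] = field(default_factory=dict)
    p_female: float = N_FEMALE / N_ENROLLED
    p_death: float = DEATH_RATE
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not self.prevalence:
            raise ValueError("empty prevalence")
        total = sum(self.prevalence.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"prevalence sums to {total}, not 1")
        for name, p in [
            ("noise_rate", self.noise_rate),
            ("multi_dx_rate", self.multi_dx_rate),
            ("p_female", self.p_female),
            ("p_death", self.p_death),
            *[(f"prevalence[{d}]", p) for d, p in self.prevalence.items()],
            *[(f"p({f}|{d})", pv[1]) for d, prof in self.finding_profiles.items() for f, pv in prof.items()],
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        if not self.age_band_probs:
            n = sum(TABLE1_AGE_BANDS.values())
            self.age_band_probs = {b: c / n for b, c in TABLE1_AGE_BANDS.items()}

    def finding_domains(self) -> dict[str, list]:
        """Observed value domain per finding (archetypes plus baseline),
        used to resample a finding under flip noise."""
        domains: dict[str, set] = {}
        for prof in self.finding_profiles.values():
            for f, (v, _p) in prof.items():
                domains.setdefault(f, set()).add(v)
        for f, v in self.baseline_findings.items():
            domains.setdefault(f, set()).add(v)
        return {f: sorted(vs, key=repr) for f, vs in domains.items()}


# ---------------------------------------------------------------------------
# archetype calibration by path-constraint back-propagation


class _FindingConstraints:
    """Accumulates (predicate, branch) outcomes for one finding and solves
    for a value satisfying all of them."""

    def __init__(self, finding: str):
        self.finding = finding
        self.fixed: list = []
        self.excluded: set = set()
        self.bool_required: bool | None = None
        self.lo: float = -math.inf  # value must be >= lo
        self.hi: float = math.inf  # value must be <= hi
        self.in_sets: list[tuple] = []

    def add(self, op: str, value, truth: bool) -> None:
        if op in ("present", "absent"):
            want = truth if op == "present" else not truth
            if self.bool_required is not None and self.bool_required != want:
                raise CalibrationError(
                    f"finding {self.finding!r} required both present and absent"
                )
            self.bool_required = want
        elif op == "equals":
            if truth:
                self.fixed.append(value)
            else:
                self.excluded.add(value)
        elif op == "in_set":
            if truth:
                self.in_sets.append(tuple(value))
            else:
                self.excluded.update(value)
        elif op == "at_least":
            if truth:
                self.lo = max(self.lo, value)
            else:
                self.hi = min(self.hi, value - 1)
        elif op == "at_most":
            if truth:
                self.hi = min(self.hi, value)
            else:
                self.lo = max(self.lo, value + 1)

    def solve(self):
        if self.bool_required is not None:
            if self.fixed and any(v != self.bool_required for v in self.fixed):
                raise CalibrationError(f"contradictory constraints on {self.finding!r}")
            return self.bool_required
        if self.fixed:
            v = self.fixed[0]
            if any(w != v for w in self.fixed) or v in self.excluded:
                raise CalibrationError(f"contradictory equality constraints on {self.finding!r}")
            if isinstance(v, (int, float)) and not (self.lo <= v <= self.hi):
                raise CalibrationError(f"value {v} for {self.finding!r} outside bounds")
            if self.in_sets and any(v not in s for s in self.in_sets):
                raise CalibrationError(f"value {v} for {self.finding!r} outside required set")
            return v
        if self.in_sets:
            candidates = [v for v in self.in_sets[0] if all(v in s for s in self.in_sets[1:])]
            for v in sorted(candidates, key=repr):
                if v not in self.excluded:
                    return v
            raise CalibrationError(f"no admissible set member for {self.finding!r}")
        if self.lo > self.hi:
            raise CalibrationError(f"empty numeric interval for {self.finding!r}")
        if math.isfinite(self.lo) or math.isfinite(self.hi):
            v = self.lo if math.isfinite(self.lo) else self.hi
            step = 1
            while v in self.excluded:
                v += step if math.isfinite(self.lo) else -step
                if not (self.lo <= v <= self.hi):
                    raise CalibrationError(f"no admissible number for {self.finding!r}")
            return v
        # only exclusions: synthesize a distinct categorical token
        token = "other"
        while token in self.excluded:
            token += "_"
        return token


def _forward_paths(alg: ClinicalAlgorithm, target: str):
    """Yield entry→target paths over forward edges as (node, branch) decision
    sequences, depth-first."""
    stack = [(alg.entry_node, [])]
    while stack:
        node_id, decisions = stack.pop()
        if node_id == target:
            yield decisions
            continue
        node = alg.nodes[node_id]
        branches = ("no", "yes") if node.kind is NodeKind.DECISION else ("next",)
        for branch in branches:  # LIFO: yes explored before no
            edge = alg.outgoing(node_id, branch)
            if edge is not None and not edge.backward:
                nxt = decisions + [(node, branch)] if branch in ("yes", "no") else decisions
                stack.append((edge.target, nxt))


def calibrate_profiles(
    alg: ClinicalAlgorithm, probability: float = 1.0
) -> dict[str, dict[str, tuple[object, float]]]:
    """Findings archetype per covered diagnosis, found by back-propagating
    the predicate outcomes along an entry→diagnosis path.

    A noise-free patient with a diagnosis' archetype traverses *alg* to
    exactly that diagnosis.  Raises :class:`CalibrationError` when a
    diagnosis is unreachable or every path to it carries contradictory
    predicates.
    """
    targets: dict[str, list[str]] = {}
    for nid in alg.dfs_order:
        n = alg.nodes[nid]
        if n.kind is NodeKind.DIAGNOSTIC_ACTION and alg.outgoing(nid, "next") is None:
            targets.setdefault(n.diagnosis, []).append(nid)
    profiles: dict[str, dict[str, tuple[object, float]]] = {}
    for dx in sorted(alg.diagnoses_covered):
        if dx not in targets:
            raise CalibrationError(f"diagnosis {dx!r} has no terminal diagnostic box")
        last_error: CalibrationError | None = None
        paths = (p for nid in targets[dx] for p in _forward_paths(alg, nid))
        for decisions in paths:
            constraints: dict[str, _FindingConstraints] = {}
            try:
                for node, branch in decisions:
                    p = node.predicate
                    c = constraints.setdefault(p.finding, _FindingConstraints(p.finding))
                    c.add(p.op, p.value, branch == "yes")
                profiles[dx] = {
                    f: (c.solve(), probability) for f, c in sorted(constraints.items())
                }
                break
            except CalibrationError as exc:
                last_error = exc
        else:
            raise CalibrationError(
                f"diagnosis {dx!r} in {alg.algorithm_id!r}: unreachable or contradictory "
                f"path constraints ({last_error})"
            )
    return profiles


# ---------------------------------------------------------------------------
# generation


def _draw_findings(spec: CohortSpec, dx: str, rng: np.random.Generator, domains) -> dict:
    profile = spec.finding_profiles.get(dx, {})
    findings = {}
    for f in sorted(set(spec.baseline_findings) | set(profile)):
        if f in profile:
            value, p = profile[f]
            if p < 1.0 and rng.random() >= p:
                value = spec.baseline_findings.get(f, UNKNOWN)
        else:
            value = spec.baseline_findings[f]
        # noise: obscure with prob eps/2, flip/resample with eps/2
        u = rng.random()
        if u < spec.noise_rate / 2:
            value = UNKNOWN
        elif u < spec.noise_rate:
            if isinstance(value, bool):
                value = not value
            else:
                others = [v for v in domains.get(f, []) if v != value]
                value = others[rng.integers(len(others))] if others else UNKNOWN
        if value is not UNKNOWN:
            findings[f] = value
    return findings


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a cohort; a pure function of the spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    dx_names = sorted(spec.prevalence)
    dx_probs = np.array([spec.prevalence[d] for d in dx_names])
    dx_probs = dx_probs / dx_probs.sum()
    in_scope = [d for d in dx_names if d not in SENTINELS]
    bands = sorted(spec.age_band_probs)
    band_probs = np.array([spec.age_band_probs[b] for b in bands])
    band_probs = band_probs / band_probs.sum()
    domains = spec.finding_domains()

    cohort = []
    for i in range(spec.n_patients):
        primary = dx_names[rng.choice(len(dx_names), p=dx_probs)]
        diagnoses = (primary,)
        if primary not in SENTINELS and len(in_scope) > 1 and rng.random() < spec.multi_dx_rate:
            others = [d for d in in_scope if d != primary]
            weights = np.array([spec.prevalence[d] for d in others])
            diagnoses = (primary, others[rng.choice(len(others), p=weights / weights.sum())])
        lo, hi = bands[rng.choice(len(bands), p=band_probs)]
        age = int(rng.integers(lo, hi + 1))
        sex = "female" if rng.random() < spec.p_female else "male"
        outcome = "died" if rng.random() < spec.p_death else "survived"
        findings = _draw_findings(spec, primary, rng, domains)
        cohort.append(
            PatientRecord(
                patient_id=f"s{i + 1:04d}",
                age=age,
                sex=sex,
                findings=findings,
                true_diagnoses=diagnoses,
                outcome=outcome,
            )
        )
    return cohort


_DEFAULT_BASELINE: dict[str, object] = {
    "cough_duration_weeks": 6,
    "smear_result": "negative",
    "xray_pattern": "normal",
    "pleural_effusion": False,
    "tap_purulent": False,
    "pericardial_effusion": False,
    "kaposi_lesions": False,
    "mediastinal_adenopathy": False,
    "cavity_air_fluid_level": False,
    "improved_on_antibiotics": False,
}


def default_spec(
    seed: int = 0,
    n_patients: int = N_ENROLLED,
    noise_rate: float = 0.0,
    calibrate_from: ClinicalAlgorithm | None = None,
) -> CohortSpec:
    """Study-shaped defaults: the disease spectrum, age bands and sex split
    of the emulated cohort, with finding profiles calibrated from a
    flowchart (the packaged locally-tailored one unless given)."""
    if calibrate_from is None:
        from .cohort import fixture_path
        from .flowchart import load_algorithm

        calibrate_from = load_algorithm(fixture_path("chuk_synthetic.yaml"))
    total = sum(TABLE1_DIAGNOSIS_COUNTS.values())  # 202: dual-diagnosis patient
    prevalence = {d: c / total for d, c in TABLE1_DIAGNOSIS_COUNTS.items()}
    return CohortSpec(
        n_patients=n_patients,
        prevalence=prevalence,
        finding_profiles=calibrate_profiles(calibrate_from),
        baseline_findings=dict(_DEFAULT_BASELINE),
        noise_rate=noise_rate,
        seed=seed,
    )


def study_shaped_cohort(calibrate_from: ClinicalAlgorithm | None = None) -> list[PatientRecord]:
    """Deterministic 201-patient cohort with *exact* study margins: the full
    diagnosis spectrum (including one dual-diagnosis patient, 9 rare and 9
    undiagnosed), 82/119 male/female, exact age-band counts and 78 deaths.

    Findings are noise-free calibrated archetypes of the primary diagnosis;
    this is the packaged cohort fixture (synthetic: the study's raw records
    were never published)."""
    if calibrate_from is None:
        from .cohort import fixture_path
        from .flowchart import load_algorithm

        calibrate_from = load_algorithm(fixture_path("chuk_synthetic.yaml"))
    profiles = calibrate_profiles(calibrate_from)
    spec = default_spec(calibrate_from=calibrate_from)
    domains = spec.finding_domains()

    diagnoses: list[tuple[str, ...]] = [("tb_smear_positive", "pcp")]  # the dual patient
    remaining = dict(TABLE1_DIAGNOSIS_COUNTS)
    remaining["tb_smear_positive"] -= 1
    remaining["pcp"] -= 1
    for dx, count in remaining.items():
        diagnoses.extend([(dx,)] * count)
    assert len(diagnoses) == N_ENROLLED

    ages = [age for (lo, hi), count in TABLE1_AGE_BANDS.items() for age in
            (lo + (j * (hi - lo + 1)) // count for j in range(count))]
    sexes = ["male"] * N_MALE + ["female"] * N_FEMALE
    deaths = round(DEATH_RATE * N_ENROLLED)
    outcomes = ["died"] * deaths + ["survived"] * (N_ENROLLED - deaths)

    def spread(items: list) -> list:
        # deterministic interleave so demographics are not aligned with the
        # diagnosis blocks
        step = 89  # coprime with 201
        out = [None] * len(items)
        for j, item in enumerate(items):
            out[(j * step) % len(items)] = item
        return out

    rng = np.random.default_rng(20020101)  # fixture identity, not a study dial
    cohort = []
    for i, (dxs, age, sex, outcome) in enumerate(
        zip(diagnoses, spread(ages), spread(sexes), spread(outcomes))
    ):
        primary = dxs[0]
        if primary in SENTINELS:
            findings = dict(spec.baseline_findings)
            if primary == RARE_DIAGNOSIS:
                # rare diseases present atypically: obscure one finding
                keys = sorted(findings)
                del findings[keys[int(rng.integers(len(keys)))]]
        else:
            findings = {f: v for f, (v, _p) in profiles[primary].items()}
            for f, v in spec.baseline_findings.items():
                findings.setdefault(f, v)
        cohort.append(
            PatientRecord(
                patient_id=f"p{i + 1:03d}",
                age=age,
                sex=sex,
                findings=findings,
                true_diagnoses=dxs,
                outcome=outcome,
            )
        )
    assert len(cohort) == N_ENROLLED
    return cohort


def load_cohort_spec(path) -> CohortSpec:
    """Read a CohortSpec from a YAML document (same tree dialect as
    flowchart files)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    profiles = {
        dx: {f: (entry["value"], float(entry.get("p", 1.0))) for f, entry in prof.items()}
        for dx, prof in doc.get("finding_profiles", {}).items()
    }
    age_bands = {
        tuple(int(x) for x in band.split("-")): float(p)
        for band, p in doc.get("age_band_probs", {}).items()
    }
    return CohortSpec(
        n_patients=int(doc["n_patients"]),
        prevalence={d: float(p) for d, p in doc["prevalence"].items()},
        finding_profiles=profiles,
        baseline_findings=doc.get("baseline_findings", {}),
        noise_rate=float(doc.get("noise_rate", 0.0)),
        multi_dx_rate=float(doc.get("multi_dx_rate", 1.0 / 183.0)),
        age_band_probs=age_bands,
        p_female=float(doc.get("p_female", N_FEMALE / N_ENROLLED)),
        p_death=float(doc.get("p_death", DEATH_RATE)),
        seed=int(doc.get("seed", 0)),
    )
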