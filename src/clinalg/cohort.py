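"""Patient records, cohort I/O, harm weights and packaged fixtures.

The unit of analysis is the *case*: a patient with k confirmed diagnoses
expands to k cases, so a 183-patient cohort with one dual-diagnosis patient
yields 184 cases.  Patients whose final diagnosis was never established, or
fell outside the disease spectrum the flowcharts cover, carry a sentinel
(``NO_DIAGNOSIS`` / ``RARE_DIAGNOSIS``) and are excluded from the restricted
sensitivity analysis while still enlarging the inclusive denominator.

Cohort files are CSV with fixed columns
``patient_id,age,sex,dx1,dx2,outcome,observed_delay_days,observed_tests,
observed_treatment`` followed by finding columns prefixed ``f_``; an empty
finding cell encodes an unknown value.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

from .flowchart import UNKNOWN

__all__ = [
    "NO_DIAGNOSIS",
    "RARE_DIAGNOSIS",
    "SENTINELS",
    "ObservedManagement",
    "PatientRecord",
    "Case",
    "HarmWeights",
    "CohortError",
    "load_cohort",
    "write_cohort",
    "expand_cases",
    "filter_in_scope",
    "load_harm_weights",
    "fixture_path",
]

NO_DIAGNOSIS = "NO_DIAGNOSIS"
RARE_DIAGNOSIS = "RARE_DIAGNOSIS"
SENTINELS = frozenset({NO_DIAGNOSIS, RARE_DIAGNOSIS})

_SEXES = ("male", "female")
_OUTCOMES = ("died", "survived", "unknown")


class CohortError(ValueError):
    """A cohort table or record violates an invariant."""


@dataclass(frozen=True)
class ObservedManagement:
    """What the ward clinicians actually did for a patient."""

    tests: tuple[str, ...]
    treatment: str | None = None
    delay_days: float | None = None

    def __post_init__(self):
        if self.delay_days is not None and self.delay_days < 0:
            raise CohortError("observed_delay_days must be >= 0")


@dataclass
class PatientRecord:
    """One enrolled patient: demographics, findings and the gold-standard
    final diagnosis/es (or a sentinel)."""

    patient_id: str
    age: float
    sex: str
    findings: dict = field(default_factory=dict)
    true_diagnoses: tuple[str, ...] = ()
    observed: ObservedManagement | None = None
    outcome: str = "unknown"

    def __post_init__(self):
        if not self.age > 15:
            raise CohortError(
                f"patient {self.patient_id!r}: age {self.age} violates the "
                "inclusion criterion (age > 15 years)"
            )
        if self.sex not in _SEXES:
            raise CohortError(f"patient {self.patient_id!r}: unknown sex code {self.sex!r}")
        if self.outcome not in _OUTCOMES:
            raise CohortError(f"patient {self.patient_id!r}: unknown outcome {self.outcome!r}")
        self.true_diagnoses = tuple(self.true_diagnoses)
        if not self.true_diagnoses:
            raise CohortError(f"patient {self.patient_id!r}: no diagnosis and no sentinel set")
        if any(d in SENTINELS for d in self.true_diagnoses) and len(self.true_diagnoses) != 1:
            raise CohortError(
                f"patient {self.patient_id!r}: a sentinel cannot be combined with diagnoses"
            )
        if len(self.true_diagnoses) > 2:
            raise CohortError(f"patient {self.patient_id!r}: more than two diagnoses")

    @property
    def is_sentinel(self) -> bool:
        return self.true_diagnoses[0] in SENTINELS


@dataclass(frozen=True)
class Case:
    """One (patient, true diagnosis) pair — the unit routed and scored."""

    patient_id: str
    true_diagnosis: str


@dataclass(frozen=True)
class HarmWeights:
    """Per-diagnosis intuitive harm weights on a 0-10 scale.

    ``omission`` is the harm of missing the diagnosis (false negative),
    ``commission`` the harm of wrongly assigning it (false positive).
    """

    weights: dict  # diagnosis -> (w_omission, w_commission)

    def __post_init__(self):
        for dx, (wo, wc) in self.weights.items():
            if not (0 <= wo <= 10 and 0 <= wc <= 10):
                raise CohortError(f"harm weights for {dx!r} outside [0, 10]: ({wo}, {wc})")

    def omission(self, dx: str) -> float:
        return self.weights[dx][0]

    def commission(self, dx: str) -> float:
        return self.weights[dx][1]

    @property
    def diagnoses(self) -> frozenset[str]:
        return frozenset(self.weights)

    def mean_omission(self) -> float:
        return sum(w[0] for w in self.weights.values()) / len(self.weights)

    def mean_commission(self) -> float:
        return sum(w[1] for w in self.weights.values()) / len(self.weights)


# ---------------------------------------------------------------------------
# cohort I/O

_FIXED_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "dx1",
    "dx2",
    "outcome",
    "observed_delay_days",
    "observed_tests",
    "observed_treatment",
)


def _parse_finding(raw: str):
    if raw == "":
        return UNKNOWN
    low = raw.lower()
    if low in ("true", "yes"):
        return True
    if low in ("false", "no"):
        return False
    try:
        f = float(raw)
        return int(f) if f == int(f) else f
    except ValueError:
        return raw


def _format_finding(value) -> str:
    if value is UNKNOWN:
        return ""
    if value is True:
        return "true"
    if value is False:
        return "false"
    return str(value)


def load_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV; reports the offending line number on a bad row."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _FIXED_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise CohortError(f"cohort file missing columns: {missing}")
        finding_cols = [c for c in reader.fieldnames if c.startswith("f_")]
        for lineno, row in enumerate(reader, start=2):
            try:
                dxs = [d for d in (row["dx1"], row["dx2"]) if d]
                observed = None
                if row["observed_tests"] or row["observed_treatment"] or row["observed_delay_days"]:
                    observed = ObservedManagement(
                        tests=tuple(t for t in row["observed_tests"].split(";") if t),
                        treatment=row["observed_treatment"] or None,
                        delay_days=float(row["observed_delay_days"])
                        if row["observed_delay_days"]
                        else None,
                    )
                findings = {
                    c[2:]: _parse_finding(row[c]) for c in finding_cols if _parse_finding(row[c]) is not UNKNOWN
                }
                records.append(
                    PatientRecord(
                        patient_id=row["patient_id"],
                        age=float(row["age"]),
                        sex=row["sex"],
                        findings=findings,
                        true_diagnoses=tuple(dxs),
                        observed=observed,
                        outcome=row["outcome"] or "unknown",
                    )
                )
            except (CohortError, KeyError, ValueError) as exc:
                raise CohortError(f"{path}, line {lineno}: {exc}") from exc
    return records


def write_cohort(records: list[PatientRecord], path) -> None:
    """Write a cohort CSV (inverse of :func:`load_cohort`)."""
    finding_cols = sorted({f for r in records for f in r.findings})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_FIXED_COLUMNS) + [f"f_{c}" for c in finding_cols])
        for r in records:
            dx1 = r.true_diagnoses[0]
            dx2 = r.true_diagnoses[1] if len(r.true_diagnoses) > 1 else ""
            obs = r.observed
            writer.writerow(
                [
                    r.patient_id,
                    int(r.age) if float(r.age) == int(r.age) else r.age,
                    r.sex,
                    dx1,
                    dx2,
                    r.outcome,
                    "" if obs is None or obs.delay_days is None else obs.delay_days,
                    "" if obs is None else ";".join(obs.tests),
                    "" if obs is None or obs.treatment is None else obs.treatment,
                ]
                + [_format_finding(r.findings.get(c, UNKNOWN)) for c in finding_cols]
            )


# ---------------------------------------------------------------------------
# case expansion and scoping


def expand_cases(cohort: list[PatientRecord]) -> list[Case]:
    """Expand multi-diagnosis patients into one case per diagnosis;
    order-preserving and deterministic."""
    cases = []
    for r in cohort:
        for dx in r.true_diagnoses:
            cases.append(Case(patient_id=r.patient_id, true_diagnosis=dx))
    return cases


def filter_in_scope(cases: list[Case], covered: frozenset | set) -> tuple[list[Case], list[Case]]:
    """Split cases into those whose true diagnosis a flowchart set covers
    and those excluded (sentinels and out-of-spectrum diagnoses)."""
    in_scope, excluded = [], []
    for c in cases:
        (in_scope if c.true_diagnosis in covered and c.true_diagnosis not in SENTINELS else excluded).append(c)
    return in_scope, excluded


def load_harm_weights(path) -> HarmWeights:
    """Read a ``diagnosis,w_omission,w_commission`` CSV."""
    weights = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            weights[row["diagnosis"]] = (float(row["w_omission"]), float(row["w_commission"]))
    if not weights:
        raise CohortError(f"harm-weight file {path} is empty")
    return HarmWeights(weights)


def fixture_path(name: str):
    """Path of a packaged fixture file (tables and flowchart encodings)."""
    return resources.files("clinalg") / "fixtures" / name
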