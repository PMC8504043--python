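"""Domain model for prescriptions, patients, wards and cohorts.

The observation unit is a single structured drug order (:class:`Prescription`);
the sampling/cluster unit is the patient (:class:`PatientRecord`), who belongs
to one of seven wards and one of two time points (before or after the switch
from paper charts to electronic order entry).

Every prescription falls into exactly one of four categories:

* ``STANDARD_PERORAL`` — regular order with a peroral route,
* ``RISKY_ROUTE``     — regular order with an invasive / error-prone route,
* ``AS_NEEDED``       — PRN order, regardless of route,
* ``OTHER``           — regular order with any remaining route
  (e.g. transdermal, ocular, nasal).

Risky routes are defined by a closed vocabulary plus a prefix rule: any
administration type whose token starts with ``intra`` (intravenous,
intrathecal, ...) counts as risky.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RouteVocabulary",
    "PrescriptionCategory",
    "TimePoint",
    "PrescriptionSource",
    "Prescription",
    "PatientRecord",
    "CohortSummary",
    "VocabularyError",
    "ReferentialIntegrityError",
    "default_route_vocabulary",
    "is_risky_route",
    "categorize_prescription",
    "summarize_cohort",
    "per_patient_category_counts",
    "matching_filter",
    "sample_sd",
]

COUNT_VARIABLES = ("total", "standard_peroral", "risky_route", "as_needed", "other")


class VocabularyError(ValueError):
    """An administration-route token outside the configured vocabulary."""


class ReferentialIntegrityError(ValueError):
    """A prescription refers to a patient that is not in the cohort."""


def _normalize_route(token: str) -> str:
    return token.strip().lower().replace("-", "").replace(" ", "").replace("_", "")


@dataclass(frozen=True)
class RouteVocabulary:
    """Closed administration-route vocabulary with a risky-route sublist.

    Tokens are normalised (lowercased, hyphens/spaces stripped) before any
    lookup, so ``"Sub-Tenon"`` and ``"subtenon"`` are the same route.
    """

    vocabulary: frozenset[str]
    risky_routes: frozenset[str]
    risky_prefixes: tuple[str, ...] = ("intra",)
    version: str = "routes-1.0"

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "RouteVocabulary":
        return cls(
            vocabulary=frozenset(_normalize_route(t) for t in cfg["vocabulary"]),
            risky_routes=frozenset(_normalize_route(t) for t in cfg["risky_routes"]),
            risky_prefixes=tuple(cfg.get("risky_prefixes", ["intra"])),
            version=cfg.get("version", "routes-custom"),
        )

    @classmethod
    def from_json(cls, path) -> "RouteVocabulary":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(json.load(fh))

    def validate(self, route: str) -> str:
        token = _normalize_route(route)
        if token not in self.vocabulary:
            raise VocabularyError(f"unknown administration route: {route!r}")
        return token

    def is_risky(self, route: str) -> bool:
        token = self.validate(route)
        if token in self.risky_routes:
            return True
        return any(token.startswith(p) for p in self.risky_prefixes)


def default_route_vocabulary() -> RouteVocabulary:
    """The packaged route vocabulary (``data/routes.json``)."""
    ref = resources.files("rxqual.data").joinpath("routes.json")
    with ref.open(encoding="utf-8") as fh:
        return RouteVocabulary.from_mapping(json.load(fh))


class PrescriptionCategory(str, Enum):
    STANDARD_PERORAL = "standard_peroral"
    RISKY_ROUTE = "risky_route"
    AS_NEEDED = "as_needed"
    OTHER = "other"


class TimePoint(str, Enum):
    PRE = "pre"
    POST = "post"


class PrescriptionSource(str, Enum):
    PAPER = "paper"
    ELECTRONIC = "electronic"


@dataclass
class Prescription:
    """One structured drug order with its documentation flags.

    Fields typed ``bool | None`` are tri-state: ``None`` means the aspect is
    not applicable to this order (e.g. no dosage interval for a one-off
    order).  ``None`` is never silently read as ``False``; a criterion that
    needs a value which is genuinely absent raises at assessment time.
    """

    prescription_id: str
    patient_id: str
    route: str
    as_needed: bool
    source: PrescriptionSource
    drug_display_name: str = ""
    trade_name_complete: bool = False
    active_substances_fully_named: bool = False
    contains_substance_abbreviation: bool | None = None
    dose_strength_documented: bool | None = None
    dosage_form_and_release_documented: bool = False
    single_dose_value: float | None = None
    single_dose_unit_documented: bool | None = None
    dosage_interval_documented: bool | None = None
    is_valid: bool = False
    is_legible: bool = False
    risky_route_stated_unabbreviated: bool | None = None
    body_site_required: bool = False
    body_site_documented: bool | None = None
    reason_documented: bool | None = None
    risk_flags: int = 0
    complete_and_unambiguous: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.source, str):
            self.source = PrescriptionSource(self.source)
        if self.single_dose_value is not None and self.single_dose_value < 0:
            raise ValueError("single_dose_value must be nonnegative")
        if self.risk_flags < 0:
            raise ValueError("risk_flags must be a nonnegative count")


@dataclass
class PatientRecord:
    """Demographics plus the patient-level documentation flags.

    ``drug_history_documented`` is tri-state: ``None`` marks patients without
    any pre-admission medication, for whom a drug history cannot apply.
    """

    patient_id: str
    ward_id: int
    time_point: TimePoint
    allergies_documented: bool = False
    age_documented: bool = False
    weight_documented: bool = False
    renal_function_documented: bool = False
    drug_history_documented: bool | None = None
    age_years: int | None = None
    sex: str | None = None
    weight_kg: float | None = None
    n_comedications: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.time_point, str):
            self.time_point = TimePoint(self.time_point)
        self.ward_id = int(self.ward_id)
        if not 1 <= self.ward_id <= 7:
            raise ValueError(f"ward_id must be in 1..7, got {self.ward_id}")
        if self.n_comedications < 0:
            raise ValueError("n_comedications must be nonnegative")


@dataclass
class CohortSummary:
    n_patients: int
    total_prescriptions: int
    mean_prescriptions_per_patient: float
    sd_prescriptions_per_patient: float
    counts_by_category: dict[PrescriptionCategory, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.counts_by_category.values()) != self.total_prescriptions:
            raise ValueError("category counts must sum to total_prescriptions")


def is_risky_route(route: str, vocab: RouteVocabulary | None = None) -> bool:
    """True iff *route* is on the risky-route list or carries an ``intra`` prefix."""
    vocab = vocab or default_route_vocabulary()
    return vocab.is_risky(route)


def categorize_prescription(
    p: Prescription, vocab: RouteVocabulary | None = None
) -> PrescriptionCategory:
    """Assign the single category of a prescription.

    PRN orders are ``AS_NEEDED`` regardless of route; regular orders split by
    route into standard-peroral, risky, or other.
    """
    vocab = vocab or default_route_vocabulary()
    token = vocab.validate(p.route)
    if p.as_needed:
        return PrescriptionCategory.AS_NEEDED
    if token == "peroral":
        return PrescriptionCategory.STANDARD_PERORAL
    if vocab.is_risky(p.route):
        return PrescriptionCategory.RISKY_ROUTE
    return PrescriptionCategory.OTHER


def sample_sd(values: Sequence[float]) -> float:
    """Sample standard deviation (n−1 denominator); 0.0 for a single value."""
    n = len(values)
    if n == 0:
        raise ValueError("sample_sd of empty sequence")
    if n == 1:
        return 0.0
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def _check_patients(
    patients: Sequence[PatientRecord], prescriptions: Iterable[Prescription]
) -> dict[str, PatientRecord]:
    index = {pat.patient_id: pat for pat in patients}
    for p in prescriptions:
        if p.patient_id not in index:
            raise ReferentialIntegrityError(
                f"prescription {p.prescription_id!r} refers to unknown patient "
                f"{p.patient_id!r}"
            )
    return index


def summarize_cohort(
    patients: Sequence[PatientRecord],
    prescriptions: Sequence[Prescription],
    vocab: RouteVocabulary | None = None,
) -> CohortSummary:
    """Cohort description: patient count, per-patient order counts, category mix."""
    if not patients:
        raise ValueError("cannot summarise an empty patient list")
    vocab = vocab or default_route_vocabulary()
    _check_patients(patients, prescriptions)
    per_patient = {pat.patient_id: 0 for pat in patients}
    counts = {c: 0 for c in PrescriptionCategory}
    for p in prescriptions:
        per_patient[p.patient_id] += 1
        counts[categorize_prescription(p, vocab)] += 1
    totals = list(per_patient.values())
    return CohortSummary(
        n_patients=len(patients),
        total_prescriptions=len(prescriptions),
        mean_prescriptions_per_patient=sum(totals) / len(totals),
        sd_prescriptions_per_patient=sample_sd(totals),
        counts_by_category=counts,
    )


def per_patient_category_counts(
    patients: Sequence[PatientRecord],
    prescriptions: Sequence[Prescription],
    vocab: RouteVocabulary | None = None,
) -> dict[str, dict[str, int]]:
    """Per-patient counts of total orders and orders per category.

    Returns ``{patient_id: {"total": n, "standard_peroral": n, ...}}`` with
    all five count variables present (zero-filled) for every patient.
    """
    vocab = vocab or default_route_vocabulary()
    _check_patients(patients, prescriptions)
    out = {
        pat.patient_id: {v: 0 for v in COUNT_VARIABLES} for pat in patients
    }
    for p in prescriptions:
        cat = categorize_prescription(p, vocab)
        out[p.patient_id]["total"] += 1
        out[p.patient_id][cat.value] += 1
    return out


def matching_filter(
    pre_counts: Mapping[str, Mapping[str, int]],
    post_patients: Sequence[PatientRecord],
    post_counts: Mapping[str, Mapping[str, int]],
) -> list[PatientRecord]:
    """Cohort-matching rule for the post arm.

    A post patient is included iff each of the five count variables (total,
    standard peroral, risky route, as needed, other) lies within one sample
    standard deviation of the corresponding pre-cohort mean.  The interval is
    closed at both ends, reading "within one standard deviation" inclusively.
    """
    if not pre_counts:
        raise ValueError("pre-cohort counts are empty")
    bounds: dict[str, tuple[float, float]] = {}
    for var in COUNT_VARIABLES:
        vals = [c[var] for c in pre_counts.values()]
        m, s = sum(vals) / len(vals), sample_sd(vals)
        bounds[var] = (m - s, m + s)
    included = []
    for pat in post_patients:
        counts = post_counts.get(pat.patient_id)
        if counts is None:
            raise ValueError(f"no counts supplied for post patient {pat.patient_id!r}")
        missing = [v for v in COUNT_VARIABLES if v not in counts]
        if missing:
            raise ValueError(
                f"patient {pat.patient_id!r} lacks count variables {missing}"
            )
        if all(bounds[v][0] <= counts[v] <= bounds[v][1] for v in COUNT_VARIABLES):
            included.append(pat)
    return included
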