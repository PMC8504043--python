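"""Twenty-criterion prescription assessment engine.

Each prescription is rated against a ruleset of 20 criteria derived from the
German good-prescribing-practice recommendation (Aktionsbündnis
Patientensicherheit).  Criteria #1–#5 ask for the presence of relevant
patient data, #6–#15 for the formal requirements of a complete prescription,
and #16–#20 for information enabling safe administration.  Every criterion is
rated MET, NOT_MET, or NOT_APPLICABLE; a fulfilment predicate is only
evaluated when the applicability predicate holds.

The default ruleset maps structured input fields to outcomes.  Sites whose
adjudication scheme differs can supply their own :class:`CriterionRule`
objects; the ruleset version string travels with every
:class:`AssessmentResult` so scored outputs remain traceable.

A required field that is missing for an applicable criterion raises
:class:`AssessmentError` naming the criterion, rather than silently counting
as NOT_MET — silent pessimism would bias every fulfilment score downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

from .prescriptions import (
    PatientRecord,
    Prescription,
    PrescriptionSource,
    RouteVocabulary,
    default_route_vocabulary,
    sample_sd,
)

__all__ = [
    "CriterionOutcome",
    "CriterionRule",
    "AssessmentResult",
    "AssessmentError",
    "default_ruleset",
    "assess_prescription",
    "assess_cohort",
    "count_not_applicable",
    "N_CRITERIA",
    "DEFAULT_RULESET_VERSION",
]

N_CRITERIA = 20
DEFAULT_RULESET_VERSION = "aps-default-1.0"


class CriterionOutcome(str, Enum):
    MET = "met"
    NOT_MET = "not_met"
    NOT_APPLICABLE = "not_applicable"


class AssessmentError(ValueError):
    """A field required by an applicable criterion is missing."""


Predicate = Callable[[Prescription, PatientRecord], bool]


@dataclass(frozen=True)
class CriterionRule:
    id: int
    description: str
    applicability: Predicate
    fulfilment: Predicate

    def __post_init__(self) -> None:
        if not 1 <= self.id <= N_CRITERIA:
            raise ValueError(f"criterion id must be 1..{N_CRITERIA}, got {self.id}")


@dataclass(frozen=True)
class AssessmentResult:
    prescription_id: str
    outcomes: tuple[CriterionOutcome, ...]
    ruleset_version: str = DEFAULT_RULESET_VERSION

    def __post_init__(self) -> None:
        if len(self.outcomes) != N_CRITERIA:
            raise ValueError(f"expected {N_CRITERIA} outcomes, got {len(self.outcomes)}")

    def n_not_applicable(self) -> int:
        return sum(o is CriterionOutcome.NOT_APPLICABLE for o in self.outcomes)


def _require(value, criterion: int, name: str):
    if value is None:
        raise AssessmentError(
            f"criterion #{criterion} is applicable but field {name!r} is missing"
        )
    return value


def _always(p: Prescription, pat: PatientRecord) -> bool:
    return True


def default_ruleset(
    vocab: RouteVocabulary | None = None,
    derived_criterion_20: bool = False,
) -> list[CriterionRule]:
    """The packaged ruleset, ids 1..20.

    Applicability conventions carried by the tri-state input fields:

    * #5 is NOT_APPLICABLE for patients with no pre-admission medication;
    * #9 is applicable only when the displayed drug name is or contains an
      active-substance designation (trade-name-only displays are exempt);
    * #11, #13, #14 are NOT_APPLICABLE when the corresponding dosage aspect
      does not exist for the formulation;
    * #15 is applicable only when a single-dose value is present;
    * #16 applies to every order with a risky administration route, whether
      regular or as-needed;
    * #17 applies only where a body site is required;
    * #19 applies only to as-needed orders.

    With ``derived_criterion_20=True``, completeness (#20) is scored as the
    conjunction of the drug/dosage criteria #10–#14 plus #16 and #17 (where
    applicable) instead of reading the explicit input flag.
    """
    vocab = vocab or default_route_vocabulary()

    def met_20_derived(p: Prescription, pat: PatientRecord) -> bool:
        parts = [
            p.trade_name_complete or p.active_substances_fully_named,
            p.dosage_form_and_release_documented,
        ]
        for v in (
            p.dose_strength_documented,
            p.dosage_interval_documented,
        ):
            if v is not None:
                parts.append(v)
        if p.single_dose_unit_documented is not None:
            parts.append(p.single_dose_value is not None and p.single_dose_unit_documented)
        if vocab.is_risky(p.route):
            parts.append(bool(_require(p.risky_route_stated_unabbreviated, 20, "risky_route_stated_unabbreviated")))
        if p.body_site_required:
            parts.append(bool(_require(p.body_site_documented, 20, "body_site_documented")))
        return all(parts)

    rules = [
        CriterionRule(1, "Allergies and intolerances documented", _always,
                      lambda p, pat: pat.allergies_documented),
        CriterionRule(2, "Age in years documented", _always,
                      lambda p, pat: pat.age_documented),
        CriterionRule(3, "Weight in kilograms documented", _always,
                      lambda p, pat: pat.weight_documented),
        CriterionRule(4, "Organ functions (eGFR and creatinine) documented", _always,
                      lambda p, pat: pat.renal_function_documented),
        CriterionRule(5, "Drug history documented",
                      lambda p, pat: pat.drug_history_documented is not None,
                      lambda p, pat: bool(pat.drug_history_documented)),
        CriterionRule(6, "The prescription is valid", _always,
                      lambda p, pat: p.is_valid),
        CriterionRule(7, "The prescription was created with the aid of a computer",
                      _always,
                      lambda p, pat: p.source is PrescriptionSource.ELECTRONIC),
        CriterionRule(8, "The prescription is easy to read", _always,
                      lambda p, pat: p.is_legible),
        CriterionRule(9, "No abbreviations for active substances",
                      lambda p, pat: p.contains_substance_abbreviation is not None,
                      lambda p, pat: not p.contains_substance_abbreviation),
        CriterionRule(10, "Full trade name or every active substance", _always,
                      lambda p, pat: p.trade_name_complete or p.active_substances_fully_named),
        CriterionRule(11, "Dose strength and unit documented",
                      lambda p, pat: p.dose_strength_documented is not None,
                      lambda p, pat: bool(p.dose_strength_documented)),
        CriterionRule(12, "Dosage form and type of release documented", _always,
                      lambda p, pat: p.dosage_form_and_release_documented),
        CriterionRule(13, "Single dose and unit documented",
                      lambda p, pat: p.single_dose_unit_documented is not None,
                      lambda p, pat: p.single_dose_value is not None
                      and bool(p.single_dose_unit_documented)),
        CriterionRule(14, "Dosage interval documented",
                      lambda p, pat: p.dosage_interval_documented is not None,
                      lambda p, pat: bool(p.dosage_interval_documented)),
        CriterionRule(15, "Single dose is a whole number",
                      lambda p, pat: p.single_dose_value is not None,
                      lambda p, pat: float(p.single_dose_value) == math.floor(p.single_dose_value)),
        CriterionRule(16, "Risky administration type stated clearly without abbreviations",
                      lambda p, pat: vocab.is_risky(p.route),
                      lambda p, pat: bool(_require(
                          p.risky_route_stated_unabbreviated, 16,
                          "risky_route_stated_unabbreviated"))),
        CriterionRule(17, "Body part and site for administration indicated",
                      lambda p, pat: p.body_site_required,
                      lambda p, pat: bool(_require(
                          p.body_site_documented, 17, "body_site_documented"))),
        CriterionRule(18, "No identifiable risks for the patient", _always,
                      lambda p, pat: p.risk_flags == 0),
        CriterionRule(19, "Reason for administration documented",
                      lambda p, pat: p.as_needed,
                      lambda p, pat: bool(_require(
                          p.reason_documented, 19, "reason_documented"))),
        CriterionRule(20, "The prescription is complete and unambiguous", _always,
                      met_20_derived if derived_criterion_20
                      else (lambda p, pat: p.complete_and_unambiguous)),
    ]
    assert [r.id for r in rules] == list(range(1, N_CRITERIA + 1))
    return rules


def ruleset_from_json(path, vocab: RouteVocabulary | None = None):
    """Load site-level ruleset configuration.

    The JSON may set ``version``, ``derived_criterion_20`` (score
    completeness from the component criteria instead of the input flag) and
    ``disabled_criteria`` (criterion ids a site does not adjudicate; they
    rate NOT_APPLICABLE everywhere).  Deeper predicate changes are made in
    code by passing custom :class:`CriterionRule` objects.

    Returns ``(rules, version)``.
    """
    import json

    with open(path, encoding="utf-8") as fh:
        cfg = json.load(fh)
    version = cfg.get("version", DEFAULT_RULESET_VERSION)
    rules = default_ruleset(
        vocab=vocab, derived_criterion_20=cfg.get("derived_criterion_20", False)
    )
    disabled = set(cfg.get("disabled_criteria", []))
    unknown = disabled - set(range(1, N_CRITERIA + 1))
    if unknown:
        raise ValueError(f"disabled_criteria contains unknown ids {sorted(unknown)}")

    def never(p, pat):
        return False

    rules = [
        CriterionRule(r.id, r.description + " [disabled]", never, never)
        if r.id in disabled else r
        for r in rules
    ]
    return rules, version


def assess_prescription(
    p: Prescription,
    pat: PatientRecord,
    rules: Sequence[CriterionRule] | None = None,
    ruleset_version: str = DEFAULT_RULESET_VERSION,
) -> AssessmentResult:
    """Rate one prescription against all 20 criteria."""
    if p.patient_id != pat.patient_id:
        raise ValueError(
            f"prescription {p.prescription_id!r} belongs to {p.patient_id!r}, "
            f"not {pat.patient_id!r}"
        )
    rules = rules if rules is not None else default_ruleset()
    if len(rules) != N_CRITERIA:
        raise ValueError(f"ruleset must contain exactly {N_CRITERIA} rules")
    outcomes = []
    for rule in rules:
        try:
            if not rule.applicability(p, pat):
                outcomes.append(CriterionOutcome.NOT_APPLICABLE)
            elif rule.fulfilment(p, pat):
                outcomes.append(CriterionOutcome.MET)
            else:
                outcomes.append(CriterionOutcome.NOT_MET)
        except AssessmentError as exc:
            raise AssessmentError(
                f"prescription {p.prescription_id!r}: {exc}"
            ) from None
    return AssessmentResult(p.prescription_id, tuple(outcomes), ruleset_version)


def assess_cohort(
    prescriptions: Sequence[Prescription],
    patients: Sequence[PatientRecord],
    rules: Sequence[CriterionRule] | None = None,
    ruleset_version: str = DEFAULT_RULESET_VERSION,
) -> list[AssessmentResult]:
    rules = rules if rules is not None else default_ruleset()
    index = {pat.patient_id: pat for pat in patients}
    results = []
    for p in prescriptions:
        try:
            pat = index[p.patient_id]
        except KeyError:
            raise AssessmentError(
                f"prescription {p.prescription_id!r} refers to unknown patient "
                f"{p.patient_id!r}"
            ) from None
        results.append(assess_prescription(p, pat, rules, ruleset_version))
    return results


def count_not_applicable(results: Sequence[AssessmentResult]) -> tuple[float, float]:
    """Mean and sample SD of the not-applicable count per prescription."""
    if not results:
        raise ValueError("no assessment results supplied")
    counts = [r.n_not_applicable() for r in results]
    return sum(counts) / len(counts), sample_sd(counts)
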