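import pandas as pd
import pytest

from rxqual.criteria import assess_cohort, default_ruleset
from rxqual.prescriptions import (
    PatientRecord,
    Prescription,
    PrescriptionSource,
    TimePoint,
    default_route_vocabulary,
)
from rxqual.simulate import SimulationConfig, simulate_record_level


@pytest.fixture(scope="session")
def vocab():
    return default_route_vocabulary()


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


def make_patient(patient_id="pat0", ward_id=1, time_point="pre", **overrides):
    defaults = dict(
        allergies_documented=True,
        age_documented=True,
        weight_documented=True,
        renal_function_documented=True,
        drug_history_documented=True,
        n_comedications=3,
    )
    defaults.update(overrides)
    return PatientRecord(
        patient_id=patient_id, ward_id=ward_id, time_point=time_point, **defaults
    )


def make_prescription(prescription_id="rx0", patient_id="pat0", **overrides):
    """A fully documented electronic order; every applicable criterion met."""
    defaults = dict(
        route="peroral",
        as_needed=False,
        source=PrescriptionSource.ELECTRONIC,
        drug_display_name="drug",
        trade_name_complete=True,
        active_substances_fully_named=True,
        contains_substance_abbreviation=False,
        dose_strength_documented=True,
        dosage_form_and_release_documented=True,
        single_dose_value=2.0,
        single_dose_unit_documented=True,
        dosage_interval_documented=True,
        is_valid=True,
        is_legible=True,
        risky_route_stated_unabbreviated=None,
        body_site_required=False,
        body_site_documented=None,
        reason_documented=None,
        risk_flags=0,
        complete_and_unambiguous=True,
    )
    defaults.update(overrides)
    return Prescription(
        prescription_id=prescription_id, patient_id=patient_id, **defaults
    )


@pytest.fixture(scope="session")
def small_sim_config():
    """A reduced cohort for fast model fits: 3 wards, 8 patients each."""
    return SimulationConfig(seed=202, n_patients_per_ward={1: 8, 2: 8, 3: 8})


@pytest.fixture(scope="session")
def record_cohort():
    """Default-condition record-level cohort (160 patients per arm)."""
    pats, rx = simulate_record_level(SimulationConfig(seed=42))
    return pats, rx


@pytest.fixture(scope="session")
def record_assessments(record_cohort):
    pats, rx = record_cohort
    return assess_cohort(rx, pats)


@pytest.fixture
def tiny_obs():
    """Seven prescriptions in three patients for likelihood oracles."""
    return pd.DataFrame({
        "y": [0.3, 0.5, 0.7, 0.9, 0.6, 0.2, 0.8],
        "patient_id": ["a", "a", "b", "b", "b", "c", "c"],
        "ward_id": [1, 1, 2, 2, 2, 1, 2],
        "time_point": ["pre", "pre", "post", "post", "post", "pre", "post"],
        "category": ["standard_peroral", "as_needed", "standard_peroral",
                     "risky_route", "other", "standard_peroral", "standard_peroral"],
        "n_comedications": [1, 1, 2, 2, 2, 1, 1],
    })
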