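"""Synthetic pre/post cohort generator.

The study data (hospital prescription charts) are not publicly available, so
this module generates cohorts carrying the statistical structure the
analysis assumes, at two fidelity levels:

* **score level** — per-prescription fulfilment scores drawn directly from
  the beta GLMM (logit-normal patient intercepts, beta observation noise),
  together with the covariates the model uses.  This is the input for
  parameter-recovery work on the model itself.

* **record level** — fully structured ``patients.csv`` / ``prescriptions.csv``
  rows whose field-level rates, pushed through the criteria engine, induce
  each criterion's fulfilment probability *in expectation*.  Criterion
  outcomes within a patient are correlated through a shared latent logit
  shift; the per-criterion logit offsets are debiased by Gauss–Hermite
  quadrature so the latent variability does not distort the marginal rates.

Defaults reproduce the study conditions: 160 patients per arm over 7 wards
(the large ward contributes 40 patients, the others 20), per-patient
prescription counts from a discretised gamma with mean 11.6 (SD 5.6) before
and 10.0 (SD 3.3) after, the observed category mixtures, per-criterion
fulfilment and applicability rates, an intervention odds ratio of 10.11 and
a patient random-intercept SD of 0.762 on the logit scale.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special

from .prescriptions import (
    PatientRecord,
    Prescription,
    PrescriptionCategory,
    PrescriptionSource,
    TimePoint,
    matching_filter,
    per_patient_category_counts,
)

__all__ = [
    "ModelParams",
    "SimulationConfig",
    "StudyBundle",
    "simulate_score_level",
    "simulate_record_level",
    "simulate_pre_post_study",
    "debiased_logit_offset",
]

_RISKY_ROUTES = ("subcutaneous", "intravenous", "epidural", "intramuscular")
_OTHER_ROUTES = ("transdermal", "ocular", "nasal")

# Per-criterion fulfilment probabilities by time point (observed cohort rates).
DEFAULT_CRITERION_PROBS: dict[int, dict[str, float]] = {
    1: {"pre": 1515 / 1850, "post": 859 / 1592},
    2: {"pre": 337 / 1850, "post": 1.0},
    3: {"pre": 1021 / 1850, "post": 1385 / 1592},
    4: {"pre": 1645 / 1850, "post": 1401 / 1592},
    5: {"pre": 750 / 1742, "post": 921 / 1489},
    6: {"pre": 1063 / 1850, "post": 1.0},
    7: {"pre": 0.0, "post": 1.0},
    8: {"pre": 1662 / 1850, "post": 1.0},
    9: {"pre": 646 / 820, "post": 568 / 774},
    10: {"pre": 1780 / 1850, "post": 1588 / 1592},
    11: {"pre": 1053 / 1843, "post": 1269 / 1586},
    12: {"pre": 234 / 1850, "post": 1535 / 1592},
    13: {"pre": 273 / 1833, "post": 1503 / 1592},
    14: {"pre": 1364 / 1833, "post": 1.0},
    15: {"pre": 1363 / 1407, "post": 1470 / 1505},
    16: {"pre": 29 / 345, "post": 1.0},
    17: {"pre": 3 / 11, "post": 3 / 5},
    18: {"pre": 1720 / 1850, "post": 1498 / 1592},
    19: {"pre": 6 / 452, "post": 289 / 362},
    20: {"pre": 1145 / 1850, "post": 1455 / 1592},
}

# Applicability / tri-state rates (cohort denominator shares).
DEFAULT_APPLICABILITY_PROBS: dict[str, dict[str, float]] = {
    "drug_history": {"pre": 1742 / 1850, "post": 1489 / 1592},
    "substance_abbreviation": {"pre": 820 / 1850, "post": 774 / 1592},
    "dose_strength": {"pre": 1843 / 1850, "post": 1586 / 1592},
    "single_dose_unit": {"pre": 1833 / 1850, "post": 1.0},
    "dosage_interval": {"pre": 1833 / 1850, "post": 1.0},
    "single_dose_value": {"pre": 1407 / 1850, "post": 1505 / 1592},
    "body_site_required": {"pre": 11 / 1850, "post": 5 / 1592},
}

DEFAULT_CATEGORY_MIX: dict[str, dict[str, float]] = {
    "pre": {"standard_peroral": 0.568, "risky_route": 0.143,
            "as_needed": 0.244, "other": 0.045},
    "post": {"standard_peroral": 0.622, "risky_route": 0.126,
             "as_needed": 0.227, "other": 0.025},
}

# Fraction of as-needed orders carrying a risky route (denominator of the
# risky-route criterion exceeds the regular risky-route count).
DEFAULT_PRN_RISKY_FRACTION = {"pre": 80 / 452, "post": 43 / 362}

_TABLE4_WARD_OR = {1: 0.80, 2: 1.04, 3: 0.53, 4: 0.82, 5: 1.29, 6: 1.44, 7: 1.21}


@dataclass
class ModelParams:
    """True parameters for score-level generation (logit scale)."""

    intercept: float = math.log(1.71)
    time_post: float = math.log(10.11)
    category: dict[str, float] = field(default_factory=lambda: {
        "risky_route": math.log(0.76),
        "as_needed": math.log(0.59),
        "other": math.log(0.87),
    })
    n_comedications: float = math.log(0.99)
    ward_effects: dict[int, float] = field(default_factory=lambda: {
        k: math.log(v) for k, v in _TABLE4_WARD_OR.items()
    })
    sigma_b: float = 0.762
    phi: float = 30.0


@dataclass
class SimulationConfig:
    """Study-condition settings; the seed fully determines every output."""

    seed: int = 0
    n_patients_per_ward: dict[int, int] = field(
        default_factory=lambda: {1: 20, 2: 20, 3: 20, 4: 20, 5: 20, 6: 20, 7: 40}
    )
    rx_count_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"pre": (11.6, 5.6), "post": (10.0, 3.3)}
    )
    category_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CATEGORY_MIX.items()}
    )
    prn_risky_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRN_RISKY_FRACTION)
    )
    criterion_probs: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CRITERION_PROBS.items()}
    )
    applicability_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_APPLICABILITY_PROBS.items()}
    )
    latent_sd: float = 0.762
    model_params: ModelParams = field(default_factory=ModelParams)
    matching_max_rounds: int = 200

    def validate(self) -> None:
        for tp, mix in self.category_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"category mix for {tp!r} sums to {total}, not 1")
            if any(not 0 <= v <= 1 for v in mix.values()):
                raise ValueError("category probabilities must lie in [0,1]")
        for src in (self.criterion_probs, self.applicability_probs):
            for key, d in src.items():
                for tp, v in d.items():
                    if not 0.0 <= v <= 1.0:
                        raise ValueError(f"probability {key}/{tp} = {v} outside [0,1]")
        for mean, sd in self.rx_count_mean_sd.values():
            if mean <= 0 or sd < 0:
                raise ValueError("prescription-count mean must be >0 and SD ≥0")
        if self.latent_sd < 0 or self.model_params.sigma_b < 0:
            raise ValueError("latent SDs must be nonnegative")
        if self.model_params.phi <= 0:
            raise ValueError("phi must be positive")

    def content_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)
        payload = json.dumps(self.__dict__, sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# latent-shift debiasing

_GH_Z, _GH_W = hermgauss(41)


def debiased_logit_offset(p: float, latent_sd: float) -> float:
    """Offset c with E[logistic(c + latent_sd·Z)] = p for Z ~ N(0,1).

    Without this correction a logit-normal latent shift pulls marginal
    Bernoulli rates toward 0.5.  Degenerate targets map to ±inf (outcomes
    become deterministic).
    """
    if p <= 0.0:
        return -math.inf
    if p >= 1.0:
        return math.inf
    if latent_sd == 0.0:
        return float(special.logit(p))

    def marginal(c):
        vals = special.expit(c + latent_sd * math.sqrt(2.0) * _GH_Z)
        return float((_GH_W * vals).sum() / math.sqrt(math.pi)) - p

    lo = special.logit(p) - 6 * latent_sd - 1
    hi = special.logit(p) + 6 * latent_sd + 1
    return float(optimize.brentq(marginal, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# score-level generation


def _draw_counts(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Discretised gamma counts, truncated at ≥ 1."""
    if sd == 0:
        return np.full(n, max(1, round(mean)), dtype=int)
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    draws = rng.gamma(shape, scale, size=n)
    return np.maximum(1, np.rint(draws)).astype(int)


def _patient_frame(config: SimulationConfig, time_point: str,
                   rng: np.random.Generator, id_prefix: str) -> pd.DataFrame:
    mean, sd = config.rx_count_mean_sd[time_point]
    rows = []
    for ward in sorted(config.n_patients_per_ward):
        for i in range(config.n_patients_per_ward[ward]):
            rows.append({"ward_id": ward})
    df = pd.DataFrame(rows)
    df["patient_id"] = [f"{id_prefix}{i:04d}" for i in range(len(df))]
    df["time_point"] = time_point
    df["n_prescriptions"] = _draw_counts(rng, len(df), mean, sd)
    return df


def simulate_score_level(config: SimulationConfig | None = None) -> pd.DataFrame:
    """Draw per-prescription transformed scores directly from the GLMM.

    Returns one row per prescription with columns ``y`` (strictly inside
    (0,1)), ``patient_id``, ``ward_id``, ``time_point``, ``category`` and
    ``n_comedications`` — exactly the table :func:`rxqual.glmm.fit` consumes.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    mp = config.model_params
    frames = []
    for tp in ("pre", "post"):
        pats = _patient_frame(config, tp, rng, id_prefix=f"{tp}_")
        b = rng.normal(0.0, mp.sigma_b, size=len(pats))
        mix = config.category_mix[tp]
        cat_names = list(mix)
        cat_p = np.array([mix[c] for c in cat_names])
        for (_, pat), b_i in zip(pats.iterrows(), b):
            n_rx = int(pat["n_prescriptions"])
            cats = rng.choice(cat_names, size=n_rx, p=cat_p)
            n_comed = n_rx - 1
            eta = (
                mp.intercept
                + (mp.time_post if tp == "post" else 0.0)
                + np.array([mp.category.get(c, 0.0) for c in cats])
                + mp.n_comedications * n_comed
                + mp.ward_effects[int(pat["ward_id"])]
                + b_i
            )
            mu = special.expit(eta)
            y = rng.beta(mu * mp.phi, (1.0 - mu) * mp.phi)
            frames.append(pd.DataFrame({
                "y": np.clip(y, 1e-9, 1 - 1e-9),
                "patient_id": pat["patient_id"],
                "ward_id": int(pat["ward_id"]),
                "time_point": tp,
                "category": cats,
                "n_comedications": n_comed,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# record-level generation


class _OffsetCache:
    def __init__(self, latent_sd: float):
        self.latent_sd = latent_sd
        self._cache: dict[float, float] = {}

    def __call__(self, p: float) -> float:
        if p not in self._cache:
            self._cache[p] = debiased_logit_offset(p, self.latent_sd)
        return self._cache[p]


def _bern_latent(rng, offset: float, u: float) -> bool:
    if math.isinf(offset):
        return offset > 0
    return bool(rng.random() < special.expit(offset + u))


def _route_for_category(rng, category: str, prn_risky: float) -> tuple[str, bool]:
    if category == "standard_peroral":
        return "peroral", False
    if category == "risky_route":
        return str(rng.choice(_RISKY_ROUTES)), False
    if category == "other":
        return str(rng.choice(_OTHER_ROUTES)), False
    # as-needed: route drawn independently of schedule
    if rng.random() < prn_risky:
        return str(rng.choice(_RISKY_ROUTES)), True
    return "peroral", True


def _simulate_arm(
    config: SimulationConfig,
    time_point: str,
    rng: np.random.Generator,
    id_prefix: str,
) -> tuple[list[PatientRecord], list[Prescription]]:
    tp = time_point
    cp = {k: v[tp] for k, v in config.criterion_probs.items()}
    ap = {k: v[tp] for k, v in config.applicability_probs.items()}
    offset = _OffsetCache(config.latent_sd)
    mix = config.category_mix[tp]
    cat_names = list(mix)
    cat_p = np.array([mix[c] for c in cat_names])
    source = PrescriptionSource.ELECTRONIC if tp == "post" else PrescriptionSource.PAPER
    prn_risky = config.prn_risky_fraction[tp]

    pats_df = _patient_frame(config, tp, rng, id_prefix)
    patients: list[PatientRecord] = []
    prescriptions: list[Prescription] = []
    for _, row in pats_df.iterrows():
        u = rng.normal(0.0, config.latent_sd)
        pid = str(row["patient_id"])
        n_rx = int(row["n_prescriptions"])
        history_applicable = rng.random() < ap["drug_history"]
        patients.append(PatientRecord(
            patient_id=pid,
            ward_id=int(row["ward_id"]),
            time_point=TimePoint(tp),
            allergies_documented=_bern_latent(rng, offset(cp[1]), u),
            age_documented=_bern_latent(rng, offset(cp[2]), u),
            weight_documented=_bern_latent(rng, offset(cp[3]), u),
            renal_function_documented=_bern_latent(rng, offset(cp[4]), u),
            drug_history_documented=(
                _bern_latent(rng, offset(cp[5]), u) if history_applicable else None
            ),
            age_years=int(rng.integers(18, 95)),
            sex="female" if rng.random() < 0.5 else "male",
            weight_kg=float(np.round(rng.normal(75, 15), 1)),
            n_comedications=n_rx - 1,
        ))
        for j in range(n_rx):
            category = str(rng.choice(cat_names, p=cat_p))
            route, as_needed = _route_for_category(rng, category, prn_risky)
            risky = category == "risky_route" or (
                as_needed and route != "peroral"
            )

            abbrev_applicable = rng.random() < ap["substance_abbreviation"]
            dose_strength_applicable = rng.random() < ap["dose_strength"]
            unit_applicable = rng.random() < ap["single_dose_unit"]
            interval_applicable = rng.random() < ap["dosage_interval"]
            body_site_required = rng.random() < ap["body_site_required"]

            # single dose value / unit: couple the value-present rate to the
            # "single dose and unit" fulfilment so both marginals hold.
            met13 = _bern_latent(rng, offset(cp[13]), u)
            p13, p15app = cp[13], ap["single_dose_value"]
            if met13:
                value_present, unit_ok = True, True
            else:
                resid = 0.0 if p13 >= 1.0 else max(0.0, (p15app - p13) / (1.0 - p13))
                value_present, unit_ok = rng.random() < resid, False
            if value_present:
                whole = _bern_latent(rng, offset(cp[15]), u)
                base = float(rng.integers(1, 4))
                single_dose_value = base if whole else base + 0.5
            else:
                single_dose_value = None

            prescriptions.append(Prescription(
                prescription_id=f"{pid}-rx{j:03d}",
                patient_id=pid,
                route=route,
                as_needed=as_needed,
                source=source,
                drug_display_name=f"drug-{rng.integers(0, 500):03d}",
                trade_name_complete=_bern_latent(rng, offset(cp[10]), u),
                active_substances_fully_named=False,
                contains_substance_abbreviation=(
                    not _bern_latent(rng, offset(cp[9]), u)
                    if abbrev_applicable else None
                ),
                dose_strength_documented=(
                    _bern_latent(rng, offset(cp[11]), u)
                    if dose_strength_applicable else None
                ),
                dosage_form_and_release_documented=_bern_latent(rng, offset(cp[12]), u),
                single_dose_value=single_dose_value,
                single_dose_unit_documented=unit_ok if unit_applicable else None,
                dosage_interval_documented=(
                    _bern_latent(rng, offset(cp[14]), u)
                    if interval_applicable else None
                ),
                is_valid=_bern_latent(rng, offset(cp[6]), u),
                is_legible=_bern_latent(rng, offset(cp[8]), u),
                risky_route_stated_unabbreviated=(
                    _bern_latent(rng, offset(cp[16]), u) if risky else None
                ),
                body_site_required=body_site_required,
                body_site_documented=(
                    _bern_latent(rng, offset(cp[17]), u)
                    if body_site_required else None
                ),
                reason_documented=(
                    _bern_latent(rng, offset(cp[19]), u) if as_needed else None
                ),
                risk_flags=(
                    0 if _bern_latent(rng, offset(cp[18]), u)
                    else 1 + int(rng.poisson(0.5))
                ),
                complete_and_unambiguous=_bern_latent(rng, offset(cp[20]), u),
            ))
    return patients, prescriptions


def simulate_record_level(
    config: SimulationConfig | None = None,
) -> tuple[list[PatientRecord], list[Prescription]]:
    """Generate structured pre and post cohorts (no matching filter)."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    pre_pat, pre_rx = _simulate_arm(config, "pre", rng, "pre_")
    post_pat, post_rx = _simulate_arm(config, "post", rng, "post_")
    return pre_pat + post_pat, pre_rx + post_rx


@dataclass
class StudyBundle:
    patients: list[PatientRecord]
    prescriptions: list[Prescription]
    manifest: dict


def simulate_pre_post_study(config: SimulationConfig | None = None) -> StudyBundle:
    """Full study bundle: pre arm, matched post arm, manifest.

    The post arm is generated ward by ward and filtered through the
    cohort-matching rule (all five per-patient prescription counts within
    one SD of the pre-cohort means); rejected patients are replaced by fresh
    draws until each ward reaches its target size.  A configurable cap on
    generation rounds guards against infeasible configurations.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    pre_pat, pre_rx = _simulate_arm(config, "pre", rng, "pre_")
    pre_counts = per_patient_category_counts(pre_pat, pre_rx)

    targets = dict(config.n_patients_per_ward)
    accepted_pat: list[PatientRecord] = []
    accepted_rx: list[Prescription] = []
    rejected = 0
    rounds = 0
    serial = 0
    while any(
        sum(1 for p in accepted_pat if p.ward_id == w) < n for w, n in targets.items()
    ):
        rounds += 1
        if rounds > config.matching_max_rounds:
            filled = {w: sum(1 for p in accepted_pat if p.ward_id == w)
                      for w in targets}
            raise RuntimeError(
                f"cohort matching infeasible after {rounds - 1} rounds; "
                f"filled {filled} of {targets} ({rejected} candidates rejected)"
            )
        cand_pat, cand_rx = _simulate_arm(config, "post", rng, f"cand{rounds:02d}_")
        cand_counts = per_patient_category_counts(cand_pat, cand_rx)
        kept = {p.patient_id for p in matching_filter(pre_counts, cand_pat, cand_counts)}
        rejected += len(cand_pat) - len(kept)
        rx_by_pat: dict[str, list[Prescription]] = {}
        for rx in cand_rx:
            rx_by_pat.setdefault(rx.patient_id, []).append(rx)
        for pat in cand_pat:
            old_id = pat.patient_id
            if old_id not in kept:
                continue
            if sum(1 for p in accepted_pat if p.ward_id == pat.ward_id) >= targets[pat.ward_id]:
                continue
            new_id = f"post_{serial:04d}"
            serial += 1
            accepted_pat.append(
                PatientRecord(**{**pat.__dict__, "patient_id": new_id})
            )
            accepted_rx.extend(
                Prescription(**{**rx.__dict__, "patient_id": new_id,
                                "prescription_id": f"{new_id}-rx{k:03d}"})
                for k, rx in enumerate(rx_by_pat.get(old_id, []))
            )
    manifest = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "n_patients_pre": len(pre_pat),
        "n_patients_post": len(accepted_pat),
        "n_prescriptions_pre": len(pre_rx),
        "n_prescriptions_post": len(accepted_rx),
        "post_candidates_rejected": rejected,
        "matching_rounds": rounds,
    }
    return StudyBundle(
        patients=pre_pat + accepted_pat,
        prescriptions=pre_rx + accepted_rx,
        manifest=manifest,
    )
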