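import math

import numpy as np
import pytest
from scipy import integrate, special, stats

from rxqual.criteria import assess_cohort
from rxqual.prescriptions import PrescriptionSource, TimePoint
from rxqual.scoring import criterion_summaries, prescription_fscore
from rxqual.simulate import (
    SimulationConfig,
    debiased_logit_offset,
    simulate_pre_post_study,
    simulate_record_level,
    simulate_score_level,
)


class TestConfig:
    def test_invalid_mix_rejected(self):
        cfg = SimulationConfig()
        cfg.category_mix["pre"]["other"] = 0.5
        with pytest.raises(ValueError, match="sums to"):
            cfg.validate()

    def test_invalid_probability_rejected(self):
        cfg = SimulationConfig()
        cfg.criterion_probs[3]["pre"] = 1.4
        with pytest.raises(ValueError):
            cfg.validate()

    def test_hash_stable_and_sensitive(self):
        a, b = SimulationConfig(seed=1), SimulationConfig(seed=1)
        assert a.content_hash() == b.content_hash()
        assert a.content_hash() != SimulationConfig(seed=2).content_hash()


class TestDebiasedOffset:
    @pytest.mark.parametrize("p", [0.02, 0.3, 0.5, 0.9, 0.997])
    def test_marginal_rate_recovered(self, p):
        sd = 0.762
        c = debiased_logit_offset(p, sd)
        marginal, _ = integrate.quad(
            lambda u: special.expit(c + u) * stats.norm.pdf(u, scale=sd), -8, 8
        )
        assert marginal == pytest.approx(p, abs=1e-9)

    def test_degenerate_targets(self):
        assert debiased_logit_offset(0.0, 0.7) == -math.inf
        assert debiased_logit_offset(1.0, 0.7) == math.inf

    def test_zero_sd_is_plain_logit(self):
        assert debiased_logit_offset(0.25, 0.0) == pytest.approx(special.logit(0.25))


class TestScoreLevel:
    def test_same_seed_identical_output(self):
        a = simulate_score_level(SimulationConfig(seed=9))
        b = simulate_score_level(SimulationConfig(seed=9))
        assert a.equals(b)

    def test_outputs_are_model_ready(self, small_sim_config):
        obs = simulate_score_level(small_sim_config)
        assert set(obs.columns) >= {"y", "patient_id", "ward_id", "time_point",
                                    "category", "n_comedications"}
        assert ((obs["y"] > 0) & (obs["y"] < 1)).all()

    def test_post_exceeds_pre_under_large_effect(self):
        for seed in range(5):
            cfg = SimulationConfig(seed=seed,
                                   n_patients_per_ward={1: 10, 2: 10, 3: 10})
            obs = simulate_score_level(cfg)
            by_tp = obs.groupby("time_point")["y"].mean()
            assert by_tp["post"] > by_tp["pre"]

    def test_zero_sigma_b_removes_patient_clustering(self):
        cfg = SimulationConfig(seed=4, n_patients_per_ward={1: 40, 2: 40})
        cfg.model_params.sigma_b = 0.0
        cfg.model_params.time_post = 0.0
        cfg.model_params.ward_effects = {1: 0.0, 2: 0.0}
        cfg.model_params.category = {k: 0.0 for k in cfg.model_params.category}
        cfg.model_params.n_comedications = 0.0
        obs = simulate_score_level(cfg)
        # patient means should spread no more than sampling noise predicts
        grp = obs.groupby("patient_id")["y"]
        between = grp.mean().var(ddof=1)
        predicted = (obs["y"].var(ddof=1) / grp.size()).mean()
        assert between < 2.5 * predicted


class TestRecordLevel:
    def test_same_seed_identical(self):
        a_p, a_r = simulate_record_level(SimulationConfig(seed=3))
        b_p, b_r = simulate_record_level(SimulationConfig(seed=3))
        assert a_p == b_p and a_r == b_r

    def test_computer_criterion_exact_by_construction(self, record_cohort,
                                                      record_assessments):
        pats, rx = record_cohort
        tp = {p.patient_id: p.time_point for p in pats}
        for res in record_assessments:
            rx_tp = tp[res.prescription_id.rsplit("-", 1)[0]]
            expected = "met" if rx_tp is TimePoint.POST else "not_met"
            assert res.outcomes[6].value == expected

    def test_sources_follow_time_point(self, record_cohort):
        pats, rx = record_cohort
        tp = {p.patient_id: p.time_point for p in pats}
        for p in rx:
            want = (PrescriptionSource.ELECTRONIC
                    if tp[p.patient_id] is TimePoint.POST
                    else PrescriptionSource.PAPER)
            assert p.source is want

    def test_perfect_probabilities_yield_perfect_scores(self):
        cfg = SimulationConfig(seed=8, n_patients_per_ward={1: 5, 2: 5})
        for c in cfg.criterion_probs.values():
            c["pre"] = c["post"] = 1.0
        for key, a in cfg.applicability_probs.items():
            if key != "body_site_required":
                a["pre"] = a["post"] = 1.0
        pats, rx = simulate_record_level(cfg)
        results = assess_cohort(rx, pats)
        pre_ids = {p.prescription_id for p in rx
                   if p.source is PrescriptionSource.PAPER}
        for res in results:
            if res.prescription_id in pre_ids:
                continue  # computer criterion is structurally unmet pre
            assert prescription_fscore(res).value == 1.0

    def test_category_mix_near_configured_shares(self, record_cohort):
        from rxqual.prescriptions import categorize_prescription
        pats, rx = record_cohort
        tp = {p.patient_id: p.time_point for p in pats}
        pre = [p for p in rx if tp[p.patient_id] is TimePoint.PRE]
        shares = {c.value: 0 for c in
                  __import__("rxqual").PrescriptionCategory}
        for p in pre:
            shares[categorize_prescription(p).value] += 1
        total = len(pre)
        for cat, want in SimulationConfig().category_mix["pre"].items():
            assert shares[cat] / total == pytest.approx(want, abs=0.04)


@pytest.fixture(scope="module")
def bundle():
    return simulate_pre_post_study(SimulationConfig(seed=7))


class TestStudyBundle:
    def test_cohort_sizes_and_large_ward(self, bundle):
        pre = [p for p in bundle.patients if p.time_point is TimePoint.PRE]
        post = [p for p in bundle.patients if p.time_point is TimePoint.POST]
        assert len(pre) == len(post) == 160
        for cohort in (pre, post):
            by_ward = {w: sum(1 for p in cohort if p.ward_id == w)
                       for w in range(1, 8)}
            assert by_ward[7] == 40
            assert all(by_ward[w] == 20 for w in range(1, 7))

    def test_manifest_provenance(self, bundle):
        m = bundle.manifest
        assert m["seed"] == 7
        assert m["n_prescriptions_pre"] == sum(
            1 for p in bundle.prescriptions
            if p.source is PrescriptionSource.PAPER)

    def test_seed_determinism_across_bundle(self):
        a = simulate_pre_post_study(SimulationConfig(seed=12))
        b = simulate_pre_post_study(SimulationConfig(seed=12))
        assert a.patients == b.patients
        assert a.prescriptions == b.prescriptions
        assert a.manifest == b.manifest

    def test_matched_post_counts_lie_within_pre_windows(self, bundle):
        from rxqual.prescriptions import (
            matching_filter,
            per_patient_category_counts,
        )
        counts = per_patient_category_counts(bundle.patients, bundle.prescriptions)
        pre_counts = {p.patient_id: counts[p.patient_id]
                      for p in bundle.patients if p.time_point is TimePoint.PRE}
        post = [p for p in bundle.patients if p.time_point is TimePoint.POST]
        kept = matching_filter(pre_counts, post, counts)
        assert len(kept) == len(post)

    def test_acceptance_rate_matches_resampling_oracle(self):
        """With post candidates drawn from the pre distributions, the
        generator's matching acceptance rate agrees with a direct
        resampling estimate of the within-1-SD window probability."""
        from rxqual.prescriptions import (
            matching_filter,
            per_patient_category_counts,
        )

        cfg = SimulationConfig(seed=55)
        cfg.rx_count_mean_sd["post"] = cfg.rx_count_mean_sd["pre"]
        cfg.category_mix["post"] = dict(cfg.category_mix["pre"])
        bundle = simulate_pre_post_study(cfg)
        m = bundle.manifest
        observed = m["n_patients_post"] / (m["n_patients_post"]
                                           + m["post_candidates_rejected"])

        # oracle: fresh identically distributed candidates vs the same windows
        pre_pat = [p for p in bundle.patients if p.time_point is TimePoint.PRE]
        pre_rx = [p for p in bundle.prescriptions
                  if p.patient_id.startswith("pre_")]
        pre_counts = per_patient_category_counts(pre_pat, pre_rx)
        accepted = total = 0
        for seed in range(56, 66):
            c2 = SimulationConfig(seed=seed)
            c2.rx_count_mean_sd["post"] = c2.rx_count_mean_sd["pre"]
            c2.category_mix["post"] = dict(c2.category_mix["pre"])
            pats, rx = simulate_record_level(c2)
            cand = [p for p in pats if p.time_point is TimePoint.POST]
            counts = per_patient_category_counts(pats, rx)
            accepted += len(matching_filter(pre_counts, cand, counts))
            total += len(cand)
        oracle = accepted / total
        assert observed == pytest.approx(oracle, abs=0.10)

    def test_infeasible_matching_raises(self):
        cfg = SimulationConfig(seed=1, matching_max_rounds=2)
        # post counts far outside the pre windows
        cfg.rx_count_mean_sd["post"] = (60.0, 1.0)
        with pytest.raises(RuntimeError, match="matching infeasible"):
            simulate_pre_post_study(cfg)
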