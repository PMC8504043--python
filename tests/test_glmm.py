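import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import special

from rxqual.glmm import (
    ModelSpec,
    beta_logpdf_mean_precision,
    build_design,
    evalue,
    fit,
    marginal_loglikelihood,
    net_interventional_effect,
    odds_ratios,
    predict_adjusted,
)
from rxqual.simulate import SimulationConfig, simulate_score_level

from .oracles import brute_force_marginal_loglik


def _obs(ward_ids, **extra):
    n = len(ward_ids)
    base = {
        "patient_id": [f"p{i}" for i in range(n)],
        "time_point": ["pre"] * n,
        "category": ["standard_peroral"] * n,
        "n_comedications": [0] * n,
        "ward_id": ward_ids,
    }
    base.update(extra)
    return pd.DataFrame(base)


class TestWeightedEffectCoding:
    def test_equal_weights_reduce_to_classical_effect_coding(self):
        obs = _obs([1, 2, 3, 1, 2, 3])
        d = build_design(obs, ModelSpec(reference_ward=3))
        ward_cols = [i for i, c in enumerate(d.columns) if c.startswith("ward_")]
        ref_rows = obs.index[obs["ward_id"] == 3]
        for r in ref_rows:
            assert list(d.X[r, ward_cols]) == [-1.0, -1.0]

    def test_unbalanced_weights(self):
        obs = _obs([1, 1, 1, 2])
        d = build_design(obs, ModelSpec(reference_ward=2))
        col = d.columns.index("ward_1")
        np.testing.assert_allclose(d.X[:3, col], 1.0)
        np.testing.assert_allclose(d.X[3, col], -3.0)  # -w1/w2 = -0.75/0.25

    def test_weighted_column_means_are_zero(self):
        rng = np.random.default_rng(0)
        obs = _obs(list(rng.integers(1, 5, size=200)))
        d = build_design(obs)
        for i, c in enumerate(d.columns):
            if c.startswith("ward_"):
                assert abs(d.X[:, i].mean()) < 1e-12

    def test_zero_prescription_ward_rejected(self):
        obs = _obs([1, 1, 2])
        with pytest.raises(ValueError):
            build_design(obs, ModelSpec(reference_ward=5))

    def test_missing_covariate_rejected(self):
        obs = _obs([1, 2, 2])
        obs.loc[1, "n_comedications"] = np.nan
        with pytest.raises(ValueError):
            build_design(obs)


class TestMarginalLikelihood:
    def test_matches_brute_force_integration(self, tiny_obs):
        d = build_design(tiny_obs)
        beta = np.array([0.2, 1.0, -0.3, -0.5, -0.1, 0.02, 0.1])[: len(d.columns)]
        y = tiny_obs["y"].to_numpy()
        for sigma, phi in [(0.762, 30.0), (0.3, 10.0), (1.5, 5.0)]:
            agq = marginal_loglikelihood(beta, sigma, phi, y, d, n_nodes=15)
            ref = brute_force_marginal_loglik(y, d, beta, sigma, phi)
            assert agq == pytest.approx(ref, abs=1e-5)

    def test_sigma_zero_reduces_to_fixed_effects_loglik(self, tiny_obs):
        d = build_design(tiny_obs)
        beta = np.zeros(len(d.columns))
        y = tiny_obs["y"].to_numpy()
        expected = beta_logpdf_mean_precision(y, special.expit(d.X @ beta), 8.0).sum()
        assert marginal_loglikelihood(beta, 0.0, 8.0, y, d) == pytest.approx(expected)

    def test_duplicating_patients_doubles_loglik(self, tiny_obs):
        doubled = pd.concat([
            tiny_obs, tiny_obs.assign(patient_id=tiny_obs["patient_id"] + "_dup")
        ], ignore_index=True)
        d1 = build_design(tiny_obs)
        d2 = build_design(doubled, ward_weights=d1.ward_weights)
        beta = np.full(len(d1.columns), 0.1)
        ll1 = marginal_loglikelihood(beta, 0.5, 12.0, tiny_obs["y"], d1)
        ll2 = marginal_loglikelihood(beta, 0.5, 12.0, doubled["y"], d2)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-10)

    def test_quadrature_converges_with_nodes(self, tiny_obs):
        d = build_design(tiny_obs)
        beta = np.full(len(d.columns), 0.2)
        y = tiny_obs["y"].to_numpy()
        lls = {k: marginal_loglikelihood(beta, 1.0, 6.0, y, d, n_nodes=k)
               for k in (5, 15, 31)}
        assert abs(lls[15] - lls[5]) >= abs(lls[31] - lls[15])
        assert abs(lls[31] - lls[15]) < 1e-5

    def test_outcome_outside_open_interval_rejected(self, tiny_obs):
        d = build_design(tiny_obs)
        y = tiny_obs["y"].to_numpy().copy()
        y[0] = 1.0
        with pytest.raises(ValueError):
            marginal_loglikelihood(np.zeros(len(d.columns)), 0.5, 5.0, y, d)


@pytest.fixture(scope="module")
def small_fit(small_sim_config):
    obs = simulate_score_level(small_sim_config)
    return obs, fit(obs, ModelSpec(n_quadrature_nodes=11))


class TestFit:
    def test_refit_is_bitwise_deterministic(self, small_sim_config):
        obs = simulate_score_level(small_sim_config)
        r1 = fit(obs, ModelSpec(n_quadrature_nodes=11), compute_vcov=False)
        r2 = fit(obs, ModelSpec(n_quadrature_nodes=11), compute_vcov=False)
        assert np.array_equal(r1.beta, r2.beta)
        assert r1.sigma_b == r2.sigma_b and r1.phi == r2.phi

    def test_recovers_generating_parameters(self, small_fit):
        _, res = small_fit
        assert res.converged
        i = res.design.columns.index("time_post")
        true = math.log(10.11)
        # single small replicate: generous window around the truth
        assert res.beta[i] - 3 * res.beta_se[i] < true < res.beta[i] + 3 * res.beta_se[i]
        assert 0.3 < res.sigma_b < 1.5
        assert 10 < res.phi < 90

    def test_vcov_symmetric_psd(self, small_fit):
        _, res = small_fit
        np.testing.assert_allclose(res.vcov, res.vcov.T)
        assert np.all(np.linalg.eigvalsh(res.vcov) > -1e-8)

    def test_rank_deficient_design_rejected(self, tiny_obs):
        obs = tiny_obs.copy()
        obs["time_point"] = "pre"  # constant column duplicates the intercept? no:
        obs["category"] = "standard_peroral"
        obs["n_comedications"] = 1  # now comedications ∝ intercept
        with pytest.raises(ValueError, match="rank"):
            fit(obs)


class TestAgainstReferenceSoftware:
    def test_matches_glmmtmb_fit(self, tmp_path):
        """Full-model cross-check against glmmTMB (beta family, logit link,
        patient random intercept) on a simulated cohort."""
        import subprocess

        cfg = SimulationConfig(seed=17, n_patients_per_ward={1: 10, 2: 10, 3: 10})
        obs = simulate_score_level(cfg)
        res = fit(obs, ModelSpec(n_quadrature_nodes=15), compute_vcov=False)
        d = res.design
        df = pd.DataFrame(d.X, columns=d.columns)
        df["y"] = obs["y"].to_numpy()
        df["pid"] = obs["patient_id"].to_numpy()
        df.to_csv(tmp_path / "glmm_in.csv", index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(glmmTMB))\n'
            f'df <- read.csv("{tmp_path / "glmm_in.csv"}")\n'
            'covs <- setdiff(colnames(df), c("y", "pid", "intercept"))\n'
            'f <- as.formula(paste("y ~", paste(covs, collapse="+"), "+ (1|pid)"))\n'
            'm <- glmmTMB(f, data = df, family = beta_family(link = "logit"))\n'
            'cat(fixef(m)$cond, "\\n")\n'
            'cat(sqrt(VarCorr(m)$cond$pid[1, 1]), sigma(m), "\\n")\n'
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        lines = out.stdout.strip().splitlines()
        ref_beta = np.array([float(v) for v in lines[0].split()])
        ref_sigma, ref_phi = (float(v) for v in lines[1].split())
        np.testing.assert_allclose(res.beta, ref_beta, atol=5e-3)
        assert res.sigma_b == pytest.approx(ref_sigma, rel=0.02)
        assert res.phi == pytest.approx(ref_phi, rel=0.02)


class TestOddsRatios:
    def test_ward_effects_weighted_to_zero(self, small_fit):
        _, res = small_fit
        effects = {e.term: e for e in odds_ratios(res)}
        w = res.design.ward_weights
        total = sum(w[k] * effects[f"ward_{k}"].coef for k in res.design.ward_levels)
        assert abs(total) < 1e-10

    def test_all_wards_reported_with_positive_cis(self, small_fit):
        _, res = small_fit
        effects = odds_ratios(res)
        terms = [e.term for e in effects]
        for k in res.design.ward_levels:
            assert f"ward_{k}" in terms
        for e in effects:
            assert 0 < e.ci_low <= e.odds_ratio <= e.ci_high

    def test_null_coefficient_gives_or_one(self, small_fit):
        _, res = small_fit
        res2 = replace(res, beta=res.beta.copy())
        i = res.design.columns.index("n_comedications")
        res2.beta[i] = 0.0
        e = {x.term: x for x in odds_ratios(res2)}["n_comedications"]
        assert e.odds_ratio == 1.0 and e.ci_low < 1.0 < e.ci_high


class TestPredictions:
    def test_population_predictions_open_interval(self, small_fit):
        obs, res = small_fit
        pred = predict_adjusted(res, obs)
        assert np.all((pred > 0) & (pred < 1))

    def test_invariant_to_reference_ward(self, small_sim_config):
        obs = simulate_score_level(small_sim_config)
        r1 = fit(obs, ModelSpec(n_quadrature_nodes=11, reference_ward=1),
                 compute_vcov=False)
        r2 = fit(obs, ModelSpec(n_quadrature_nodes=11, reference_ward=3),
                 compute_vcov=False)
        np.testing.assert_allclose(
            predict_adjusted(r1, obs), predict_adjusted(r2, obs), atol=1e-5
        )

    def test_increasing_time_coefficient_raises_post_predictions(self, small_fit):
        obs, res = small_fit
        i = res.design.columns.index("time_post")
        base = predict_adjusted(res, obs)
        boosted = replace(res, beta=res.beta.copy())
        boosted.beta[i] += 0.5
        up = predict_adjusted(boosted, obs)
        post = (obs["time_point"] == "post").to_numpy()
        assert np.all(up[post] > base[post])
        np.testing.assert_allclose(up[~post], base[~post])

    def test_conditional_predictions_shift_by_patient(self, small_fit):
        obs, res = small_fit
        pop = predict_adjusted(res, obs)
        cond = predict_adjusted(res, obs, conditional=True)
        assert cond.shape == pop.shape
        assert not np.allclose(cond, pop)  # random intercepts move predictions


class TestNetEffect:
    def test_null_time_effect_gives_near_zero_differences(self, small_fit):
        obs, res = small_fit
        nulled = replace(res, beta=res.beta.copy())
        nulled.beta[res.design.columns.index("time_post")] = 0.0
        effects = net_interventional_effect(nulled, obs)
        for v in effects.values():
            assert abs(v) < 5.0  # only covariate imbalance remains

    def test_differences_bounded(self, small_fit):
        obs, res = small_fit
        for v in net_interventional_effect(res, obs).values():
            assert -100 < v < 100

    def test_large_positive_effect_on_every_category(self, small_fit):
        obs, res = small_fit
        for v in net_interventional_effect(res, obs).values():
            assert v > 10.0


class TestEvalue:
    @pytest.mark.parametrize("odds_ratio,expected", [
        (10.11, 19.7),
        (1.0, 1.0),
        (4.0, 4 + math.sqrt(12)),
    ])
    def test_examples(self, odds_ratio, expected):
        assert evalue(odds_ratio) == pytest.approx(expected, abs=0.05)

    def test_protective_estimates_are_inverted(self):
        assert evalue(0.5) == pytest.approx(evalue(2.0))

    def test_strictly_increasing_above_one(self):
        grid = np.linspace(1.0, 20.0, 200)
        vals = [evalue(x) for x in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            evalue(0.0)
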