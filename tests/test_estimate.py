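"""Estimator: draws, logit kernel, simulated likelihood vs oracles,
cross-implementation checks, sandwich SEs, WTP."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from huimin_hcm.design import default_attributes
from huimin_hcm.estimate import (
    ChoiceArrays,
    DrawConfig,
    EstimationResult,
    ModelSpec,
    _loglik_core,
    _Packer,
    _pvec_from_params,
    _raw_from_tau,
    _tau_from_raw,
    conditional_utility,
    enumerate_interactions,
    fit_mnl,
    halton_sequence,
    make_draws,
    mnl_probabilities,
    person_likelihood,
    prepare_arrays,
    robust_se,
    significance_stars,
    simulated_loglik,
    wtp,
)
from huimin_hcm.preprocess import filter_dataset
from huimin_hcm.simulate import (
    INDICATOR_NAMES,
    SurveyDataset,
    default_true_params,
    simulate_survey,
)

from test_simulate import zeroed_params


# ---------------------------------------------------------------------------
# Draws
# ---------------------------------------------------------------------------

class TestHalton:
    def test_unscrambled_base2_prefix(self):
        u = norm.cdf(halton_sequence(1, 1, 3, scramble=False))
        assert np.allclose(u.ravel(), [0.5, 0.25, 0.75])

    def test_marginal_moments(self):
        draws = halton_sequence(1, 5, 10_000, seed=1)
        assert abs(draws.mean()) < 0.01
        assert abs(draws.std() - 1.0) < 0.01

    def test_individual_blocks_disjoint(self):
        both = halton_sequence(2, 2, 50, seed=2)
        merged = halton_sequence(1, 2, 100, seed=2)
        assert np.allclose(both.reshape(100, 2), merged.reshape(100, 2))
        assert not np.allclose(both[0], both[1])

    def test_dimension_cap(self):
        with pytest.raises(ValueError):
            halton_sequence(1, 21, 10)

    def test_deterministic_per_seed(self):
        assert np.allclose(halton_sequence(3, 4, 20, seed=5),
                           halton_sequence(3, 4, 20, seed=5))

    @pytest.mark.parametrize("scheme", ["scrambled-halton", "mlhs", "pseudo-random"])
    def test_make_draws_shapes(self, scheme):
        d = make_draws(4, 3, 7, DrawConfig(scheme=scheme, n_draws=16, seed=3))
        assert d["eta"].shape == (4, 16, 3)
        assert d["xi"].shape == (4, 16, 7)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            DrawConfig(n_draws=0)
        with pytest.raises(ValueError):
            DrawConfig(scheme="sobol")


# ---------------------------------------------------------------------------
# Elementary kernel pieces
# ---------------------------------------------------------------------------

class TestMnlProbabilities:
    def test_uniform(self):
        assert np.allclose(mnl_probabilities([0.0, 0.0, 0.0]), 1 / 3)

    def test_log_two_closed_form(self):
        assert np.allclose(mnl_probabilities([np.log(2), 0.0, 0.0]),
                           [0.5, 0.25, 0.25])

    def test_location_invariance(self):
        u = np.array([0.3, -1.2, 2.0])
        assert np.allclose(mnl_probabilities(u), mnl_probabilities(u + 57.0))

    def test_dominant_limit(self):
        p = mnl_probabilities([0.0, 40.0, 80.0])
        assert p[2] == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            mnl_probabilities([0.0, np.nan, 1.0])


class TestConditionalUtility:
    def covariates(self):
        return {"gender": 0, "age_mid": 0, "age_old": 0, "residence": 0,
                "catastrophic": 0, "private_insurance": 0}

    def test_all_zero(self, attrs):
        p = zeroed_params()
        prof = {"premium": 170.0, "government": "moderate", "deductible": 150_000.0,
                "reimbursement": 65.0, "value_added": "basic"}
        v = conditional_utility(prof, self.covariates(),
                                {"HR": 0.4, "AW": -1.0, "VAL": 2.0}, {}, p, attrs)
        assert v == 0.0

    def test_premium_only(self, attrs):
        p = zeroed_params()
        p.b["premium"] = -0.007
        prof = {"premium": 130.0, "government": "commercial", "deductible": 120_000.0,
                "reimbursement": 50.0, "value_added": "basic"}
        p2 = zeroed_params()
        p2.b["premium"] = -0.007
        # strip every other coded column by zero coding: only premium nonzero
        prof0 = dict(prof)
        v = conditional_utility(prof0, self.covariates(),
                                {"HR": 0, "AW": 0, "VAL": 0}, {}, p2, attrs)
        # reimbursement/deductible coded but their coefficients are 0
        assert v == pytest.approx(-0.007 * 130, abs=1e-12)
        assert v == pytest.approx(-0.91)

    def test_latent_interaction_term(self, attrs):
        p = zeroed_params()
        p.theta = {("government:strong", "HR"): -0.178}
        prof = {"premium": 0.0, "government": "strong", "deductible": 0.0,
                "reimbursement": 0.0, "value_added": "basic"}
        # premium/deductible/reimbursement enter at level 0 so only the
        # strong-involvement dummy contributes
        prof["premium"] = 130.0  # nonzero level but zero coefficient
        v = conditional_utility(prof, self.covariates(),
                                {"HR": 1.0, "AW": 0.0, "VAL": 0.0}, {}, p, attrs)
        assert v == pytest.approx(-0.178)

    def test_optout_utility(self, attrs):
        p = zeroed_params(delta=-3.889)
        p.phi = {"HR": 0.125, "AW": 0.170, "VAL": -0.004}
        v = conditional_utility(None, self.covariates(),
                                {"HR": 1.0, "AW": 2.0, "VAL": 3.0}, {}, p, attrs)
        assert v == pytest.approx(-3.889 + 0.125 + 0.340 - 0.012)


class TestPersonLikelihood:
    def test_uniform_factorization(self, filtered_small, attrs):
        p = zeroed_params()
        p.tau = np.tile([-2.0, -0.5, 0.5, 2.0], (11, 1))
        rid = filtered_small.respondents["respondent"].iloc[0]
        records = filtered_small.choices[filtered_small.choices["respondent"] == rid]
        cov = filtered_small.respondents.set_index("respondent").loc[rid].to_dict()
        inds = filtered_small.indicators.set_index("respondent").loc[rid].to_dict()
        draw = {"eta": np.zeros(3), "xi": {}}
        like = person_likelihood(records, inds, cov, draw, p, attrs)
        # zero loadings: each indicator prob depends on thresholds only
        probs = np.diff(np.r_[0, expit([-2, -0.5, 0.5, 2]), 1])
        ind_part = np.prod([probs[int(inds[i]) - 1] for i in INDICATOR_NAMES])
        assert like == pytest.approx((1 / 3) ** 6 * ind_part, rel=1e-9)

    def test_hand_oracle_single_task(self, attrs):
        # one task, one indicator, worked through with explicit arithmetic
        p = zeroed_params()
        p.b["premium"] = -0.01
        p.delta = -1.0
        p.zeta = np.r_[2.0, np.zeros(10)]
        p.tau = np.tile([-2.0, -0.5, 0.5, 2.0], (11, 1))
        cols = ["premium", "government:moderate", "government:strong", "deductible",
                "reimbursement", "value_added:expanded1", "value_added:expanded2",
                "value_added:expanded3"]
        rows = []
        for alt, premium, chosen, opt in [(1, 130, 1, 0), (2, 210, 0, 0), (3, 0, 0, 1)]:
            row = {"respondent": 1, "set_id": 1, "alt_id": alt, "is_qc": 0,
                   "is_optout": opt, "chosen": chosen}
            row.update({c: 0.0 for c in cols})
            row["premium"] = premium if not opt else 0.0
            rows.append(row)
        records = pd.DataFrame(rows)
        cov = {"gender": 1, "age_mid": 0, "age_old": 0, "residence": 0,
               "catastrophic": 0, "private_insurance": 0}
        inds = {"hr1": 4}
        draw = {"eta": np.array([0.5, 0.0, 0.0]), "xi": {}}
        like = person_likelihood(records, inds, cov, draw, p, attrs)
        # by hand: utilities -1.3, -2.1, -1.0; HR = 0.5, u = 1.0
        u = np.array([-1.3, -2.1, -1.0])
        pc = np.exp(u[0]) / np.exp(u).sum()
        ind = expit(2.0 - 1.0) - expit(0.5 - 1.0)
        assert like == pytest.approx(pc * ind, rel=1e-12)

    def test_monotone_in_chosen_disutility(self, attrs, filtered_small):
        p = zeroed_params()
        p.tau = np.tile([-2.0, -0.5, 0.5, 2.0], (11, 1))
        rid = filtered_small.respondents["respondent"].iloc[0]
        records = filtered_small.choices[filtered_small.choices["respondent"] == rid]
        cov = filtered_small.respondents.set_index("respondent").loc[rid].to_dict()
        inds = filtered_small.indicators.set_index("respondent").loc[rid].to_dict()
        draw = {"eta": np.zeros(3), "xi": {}}
        base = person_likelihood(records, inds, cov, draw, p, attrs)
        p.delta = -2.0  # pushes probability toward non-opt-out alternatives
        shifted = person_likelihood(records, inds, cov, draw, p, attrs)
        chosen_opt = records[(records["chosen"] == 1) & (records["is_optout"] == 1)]
        if len(chosen_opt) == 0:
            assert shifted > base


class TestVectorizedKernelAgreesWithReference:
    def test_simulated_loglik_matches_person_likelihood_loop(self, attrs, study_design,
                                                             true_params):
        ds = simulate_survey(study_design, true_params, n=12,
                             inattentive_fraction=0.0, seed=21)
        f, _ = filter_dataset(ds)
        spec = ModelSpec.hcm(attrs, interactions=sorted(true_params.theta.keys()))
        cfg = DrawConfig(n_draws=5, seed=13)
        ll_vec = simulated_loglik(f, true_params, cfg, spec=spec)

        packer = _Packer(spec)
        arrays = prepare_arrays(f)
        d = make_draws(len(arrays.respondents), 3, packer.S, cfg)
        total = 0.0
        for i, rid in enumerate(arrays.respondents):
            records = f.choices[f.choices["respondent"] == rid]
            cov = f.respondents.set_index("respondent").loc[rid].to_dict()
            inds = f.indicators.set_index("respondent").loc[rid].to_dict()
            sims = []
            for r in range(cfg.n_draws):
                draw = {"eta": d["eta"][i, r],
                        "xi": dict(zip(spec.random_slots, d["xi"][i, r]))}
                sims.append(person_likelihood(records, inds, cov, draw,
                                              true_params, attrs))
            total += np.log(np.mean(sims))
        assert ll_vec == pytest.approx(total, rel=1e-10)


# ---------------------------------------------------------------------------
# Simulated likelihood properties
# ---------------------------------------------------------------------------

def closed_form_mnl_loglik(arrays: ChoiceArrays, beta_fixed: np.ndarray) -> float:
    """Independent closed-form MNL log-likelihood (plain loops)."""
    total = 0.0
    n, T, J, Kc = arrays.X.shape
    for i in range(n):
        for t in range(T):
            u = arrays.X[i, t] @ beta_fixed
            u = u - u.max()
            p = np.exp(u) / np.exp(u).sum()
            total += np.log(p[arrays.y[i, t]])
    return total


class TestSimulatedLoglik:
    def test_degenerate_equals_closed_form_mnl(self, attrs, study_design, true_params):
        ds = simulate_survey(study_design, true_params, n=50,
                             inattentive_fraction=0.0, seed=23)
        f, _ = filter_dataset(ds)
        spec = ModelSpec.mixed_logit(attrs)
        packer = _Packer(spec)
        arrays = prepare_arrays(f)
        rng = np.random.default_rng(1)
        beta_fixed = rng.normal(scale=0.2, size=packer.Kc)
        pvec = packer.pack(beta_fixed=beta_fixed, sigma=np.zeros(packer.S),
                           theta=np.zeros(0))
        d = make_draws(len(arrays.respondents), 0, packer.S,
                       DrawConfig(n_draws=64, seed=3))
        ll, _, _ = _loglik_core(pvec, arrays, packer, d, want_grad=False)
        assert ll == pytest.approx(closed_form_mnl_loglik(arrays, beta_fixed),
                                   abs=1e-10)

    def test_sigma_sign_flip_invariance(self, attrs, study_design, true_params):
        ds = simulate_survey(study_design, true_params, n=20,
                             inattentive_fraction=0.0, seed=24)
        f, _ = filter_dataset(ds)
        spec = ModelSpec.hcm(attrs, interactions=sorted(true_params.theta.keys()))
        packer = _Packer(spec)
        arrays = prepare_arrays(f)
        d = make_draws(len(arrays.respondents), 3, packer.S, DrawConfig(n_draws=16, seed=4))
        pvec = _pvec_from_params(true_params, packer)
        ll0, _, _ = _loglik_core(pvec, arrays, packer, d, want_grad=False)
        for s in range(packer.S):
            flipped = pvec.copy()
            j = packer.names.index(f"sd:{spec.random_slots[s]}")
            flipped[j] = -flipped[j]
            ll1, _, _ = _loglik_core(flipped, arrays, packer, d, want_grad=False)
            assert ll1 == pytest.approx(ll0, rel=1e-14)

    def test_respondent_permutation_invariance(self, study_design, true_params):
        ds = simulate_survey(study_design, true_params, n=25,
                             inattentive_fraction=0.0, seed=25)
        f, _ = filter_dataset(ds)
        cfg = DrawConfig(n_draws=16, seed=5)
        base = simulated_loglik(f, true_params, cfg)
        shuffled = SurveyDataset(
            respondents=f.respondents.sample(frac=1, random_state=2).reset_index(drop=True),
            indicators=f.indicators.sample(frac=1, random_state=3).reset_index(drop=True),
            choices=f.choices.sample(frac=1, random_state=4).reset_index(drop=True),
            design=f.design,
        )
        assert simulated_loglik(shuffled, true_params, cfg) == pytest.approx(
            base, rel=1e-12)

    def test_alternative_relabel_invariance(self, study_design, true_params):
        ds = simulate_survey(study_design, true_params, n=25,
                             inattentive_fraction=0.0, seed=26)
        f, _ = filter_dataset(ds)
        cfg = DrawConfig(n_draws=16, seed=6)
        base = simulated_loglik(f, true_params, cfg)
        cho = f.choices.copy()
        swap = cho["alt_id"].map({1: 2, 2: 1, 3: 3})
        cho["alt_id"] = swap
        relabeled = SurveyDataset(respondents=f.respondents, indicators=f.indicators,
                                  choices=cho, design=f.design)
        assert simulated_loglik(relabeled, true_params, cfg) == pytest.approx(
            base, rel=1e-12)

    def test_halton_gap_shrinks_with_draws(self, study_design, true_params):
        ds = simulate_survey(study_design, true_params, n=30,
                             inattentive_fraction=0.0, seed=27)
        f, _ = filter_dataset(ds)
        lls = [simulated_loglik(f, true_params, DrawConfig(n_draws=R, seed=7))
               for R in (64, 256, 1024, 4096)]
        gaps = np.abs(np.diff(lls))
        assert gaps[-1] < gaps[0]


# ---------------------------------------------------------------------------
# Cross-implementation oracle: statsmodels conditional logit
# ---------------------------------------------------------------------------

class TestMnlCrossCheck:
    def test_matches_statsmodels_conditional_logit(self, filtered_small):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        res = fit_mnl(filtered_small, compute_se=False)
        exp = filtered_small.choices
        exp = exp[exp["is_qc"] == 0]
        cols = list(res.spec.coded_cols) + ["is_optout"]
        groups = exp["respondent"].astype(str) + "_" + exp["set_id"].astype(str)
        sm_fit = ConditionalLogit(exp["chosen"].to_numpy(),
                                  exp[cols].to_numpy(float),
                                  groups=groups.to_numpy()).fit(disp=False)
        ours = np.array([res.get(f"b:{c}") for c in res.spec.coded_cols]
                        + [res.get("optout_asc")])
        assert np.allclose(ours, sm_fit.params, atol=1e-4)


# ---------------------------------------------------------------------------
# Sandwich standard errors
# ---------------------------------------------------------------------------

class TestRobustSE:
    def test_duplicated_sample_scales_robust_se(self, filtered_small):
        res1 = fit_mnl(filtered_small, compute_se=True)
        resp = filtered_small.respondents
        shift = int(resp["respondent"].max()) + 1000
        resp2 = resp.copy()
        resp2["respondent"] += shift
        ind2 = filtered_small.indicators.copy()
        ind2["respondent"] += shift
        cho2 = filtered_small.choices.copy()
        cho2["respondent"] += shift
        doubled = SurveyDataset(
            respondents=pd.concat([resp, resp2], ignore_index=True),
            indicators=pd.concat([filtered_small.indicators, ind2], ignore_index=True),
            choices=pd.concat([filtered_small.choices, cho2], ignore_index=True),
            design=filtered_small.design,
        )
        res2 = fit_mnl(doubled, compute_se=True)
        ratio = res2.robust_se / res1.robust_se
        assert np.allclose(ratio, 1 / np.sqrt(2), rtol=0.02)

    def test_information_equality_large_n(self, study_design, true_params):
        # correctly specified MNL data: robust and classical SEs agree
        p = zeroed_params()
        p.b = dict(true_params.b)
        p.delta = true_params.delta
        ds = simulate_survey(study_design, p, n=2000, inattentive_fraction=0.0, seed=28)
        res = fit_mnl(ds if not study_design.qc_sets else filter_dataset(ds)[0],
                      compute_se=True)
        ratio = res.robust_se / res.classical_se
        assert np.all((ratio > 0.8) & (ratio < 1.2))

    def test_hand_computed_sandwich_toy(self, filtered_small):
        # independent sandwich computation from explicit per-task scores
        res = fit_mnl(filtered_small, compute_se=True)
        arrays = prepare_arrays(filtered_small)
        beta = res.pvec
        n, T, J, Kc = arrays.X.shape
        scores = np.zeros((n, Kc))
        H = np.zeros((Kc, Kc))
        for i in range(n):
            for t in range(T):
                X = arrays.X[i, t]
                u = X @ beta
                u -= u.max()
                pr = np.exp(u) / np.exp(u).sum()
                scores[i] += X[arrays.y[i, t]] - pr @ X
                H -= X.T @ (np.diag(pr) - np.outer(pr, pr)) @ X
        B = scores.T @ scores
        Hinv = np.linalg.inv(-H)
        se_hand = np.sqrt(np.diag(Hinv @ B @ Hinv))
        assert np.allclose(res.robust_se, se_hand, rtol=1e-3)

    def test_standalone_robust_se_matches_fit(self, filtered_small):
        res = fit_mnl(filtered_small, compute_se=True)
        se0 = res.robust_se.copy()
        se1 = robust_se(res, filtered_small)
        # two finite-difference Hessians (scaled vs raw parameterization)
        assert np.allclose(se0, se1, rtol=1e-3)


# ---------------------------------------------------------------------------
# WTP
# ---------------------------------------------------------------------------

def toy_result(pvec, names, cov):
    return EstimationResult(
        estimates=None, param_names=list(names), pvec=np.asarray(pvec, float),
        robust_se=np.sqrt(np.diag(cov)), classical_se=None, loglik=0.0,
        n_individuals=0, n_tasks=0, gradient_norm=0.0, converged=True,
        draw_config=None, spec=ModelSpec.mnl(default_attributes()),
        robust_cov=np.asarray(cov, float),
    )


class TestWtp:
    def test_published_ratio(self):
        cov = np.diag([1e-8, 1e-4])
        res = toy_result([-0.007, 0.880], ["b:premium", "b:government:strong"], cov)
        table = wtp(res)
        assert table["wtp"].iloc[0] == pytest.approx(0.880 / 0.007, rel=1e-12)
        assert table["wtp"].iloc[0] == pytest.approx(125.71, abs=0.01)

    def test_zero_coefficient_zero_wtp(self):
        res = toy_result([-0.007, 0.0], ["b:premium", "b:deductible"],
                         np.diag([1e-8, 1e-6]))
        assert wtp(res)["wtp"].iloc[0] == 0.0

    def test_premium_near_zero_signals(self):
        res = toy_result([1e-9, 0.5], ["b:premium", "b:deductible"], np.eye(2) * 1e-6)
        with pytest.raises(ValueError, match="premium"):
            wtp(res)

    def test_delta_method_matches_parametric_bootstrap(self):
        est = np.array([-0.007, 0.880])
        cov = np.array([[1.2e-6, -2e-6], [-2e-6, 9e-3]]) * 0.01
        res = toy_result(est, ["b:premium", "b:government:strong"], cov)
        se_delta = wtp(res)["se"].iloc[0]
        rng = np.random.default_rng(12)
        sims = rng.multivariate_normal(est, cov, size=200_000)
        boot = -sims[:, 1] / sims[:, 0]
        assert se_delta == pytest.approx(boot.std(), rel=0.05)


# ---------------------------------------------------------------------------
# Misc estimator plumbing
# ---------------------------------------------------------------------------

class TestPlumbing:
    def test_interaction_enumeration(self):
        assert len(enumerate_interactions()) == 7 * 9 == 63

    def test_tau_reparameterization_round_trip(self):
        tau = np.tile([-2.0, -0.5, 0.5, 2.0], (11, 1))
        assert np.allclose(_tau_from_raw(_raw_from_tau(tau)), tau)

    def test_significance_stars(self):
        assert significance_stars(0.004) == "***"
        assert significance_stars(0.02) == "**"
        assert significance_stars(0.07) == "*"
        assert significance_stars(0.2) == ""

    def test_result_table_layout(self, filtered_small):
        res = fit_mnl(filtered_small, compute_se=True)
        table = res.table()
        assert {"parameter", "estimate", "robust_se", "p_value", "stars"} <= set(table)
        assert len(table) == len(res.param_names)
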