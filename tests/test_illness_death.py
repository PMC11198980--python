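"""Core model: hazards, conditional and marginal likelihoods (against
independent quadrature and naive-implementation oracles), fitting, and the
cumulative incidence function."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from semicompete import (
    IllnessDeathParams,
    cif_nonterminal,
    fit_mle,
    generate_cohort,
    marginal_loglik,
    recovery_config,
    subject_loglik_conditional,
    transition_hazard,
)
from semicompete.illness_death import (
    FitOptions,
    TIE_HALF_DAY,
    _negloglik_and_grad,
    _pack,
    _prepare_arrays,
)

from conftest import make_cohort


def params_of(beta1, beta2, beta3, kappa, lam, theta=0.0, clock="semi-markov"):
    return IllnessDeathParams(beta1, beta2, beta3, kappa, lam, theta, clock)


# ---------------------------------------------------------------------------
# independent oracles, deliberately written in plain scalar form


def naive_weibull_ph_loglik(cohort, params):
    """Independent no-frailty log-likelihood: sum of three transition-wise
    Weibull proportional-hazards likelihoods, looped subject by subject."""
    total = 0.0
    k, lam = params.kappa, params.lam
    for _, r in cohort.data.iterrows():
        x = r[cohort.covariate_names].to_numpy(float)
        e1, e2, e3 = np.exp(x @ params.beta1), np.exp(x @ params.beta2), np.exp(
            x @ params.beta3
        )
        y1, d1, y2, d2 = r["y1"], int(r["delta1"]), r["y2"], int(r["delta2"])
        # transition 1: at risk on (0, y1]
        total += -lam[0] * y1 ** k[0] * e1
        if d1:
            total += np.log(k[0] * lam[0] * y1 ** (k[0] - 1.0) * e1)
        # transition 2: at risk on (0, y1] (illness removes the subject)
        total += -lam[1] * y1 ** k[1] * e2
        if not d1 and d2:
            total += np.log(k[1] * lam[1] * y2 ** (k[1] - 1.0) * e2)
        # transition 3: at risk after illness only
        if d1:
            y2a = y2 + TIE_HALF_DAY if y2 <= y1 else y2
            if params.clock == "semi-markov":
                s = y2a - y1
                total += -lam[2] * s ** k[2] * e3
                if d2:
                    total += np.log(k[2] * lam[2] * s ** (k[2] - 1.0) * e3)
            else:
                total += -lam[2] * (y2a ** k[2] - y1 ** k[2]) * e3
                if d2:
                    total += np.log(k[2] * lam[2] * y2a ** (k[2] - 1.0) * e3)
    return total


def quadrature_marginal_loglik(subject, params):
    """Numerically integrate the conditional likelihood against the gamma
    frailty density (mean 1, variance theta)."""
    th = params.theta
    shape, rate = 1.0 / th, 1.0 / th

    def integrand(a):
        return np.exp(
            subject_loglik_conditional(subject, a, params)
        ) * stats.gamma.pdf(a, shape, scale=1.0 / rate)

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=400)
    return np.log(val)


def random_subject_and_params(rng, p=2):
    """A random valid observation pattern with random Weibull parameters."""
    x = rng.normal(0, 0.5, size=p)
    pattern = rng.integers(0, 4)
    d1, d2 = pattern // 2, pattern % 2
    y1 = rng.uniform(0.5, 3.0)
    y2 = y1 + rng.uniform(0.2, 3.0) if d1 else y1
    subject = {"y1": y1, "delta1": d1, "y2": y2, "delta2": d2, "x": x}
    params = params_of(
        rng.normal(0, 0.4, p), rng.normal(0, 0.4, p), rng.normal(0, 0.4, p),
        kappa=rng.uniform(0.7, 1.8, 3), lam=rng.uniform(0.05, 0.6, 3),
        theta=rng.uniform(0.05, 3.0),
        clock="semi-markov" if rng.random() < 0.5 else "markov",
    )
    return subject, params


def subject_df(subjects):
    rows = []
    for i, s in enumerate(subjects):
        row = {"id": f"s{i}", "y1": s["y1"], "delta1": s["delta1"],
               "y2": s["y2"], "delta2": s["delta2"]}
        for j, v in enumerate(np.atleast_1d(s["x"])):
            row[f"x{j+1}"] = v
        rows.append(row)
    return make_cohort(pd.DataFrame(rows))


# ---------------------------------------------------------------------------


class TestTransitionHazard:
    def test_exponential_baseline_is_constant(self):
        pr = params_of([0.0], [0.0], [0.0], [1, 1, 1], [0.01, 0.02, 0.03])
        for t in (0.5, 10.0, 500.0):
            assert transition_hazard(1, t, [0.0], 1.0, pr) == pytest.approx(0.01)

    def test_frailty_is_multiplicative(self):
        pr = params_of([0.3], [0.0], [0.0], [1.5, 1, 1], [0.01, 0.02, 0.03])
        h1 = transition_hazard(1, 2.0, [1.0], 1.0, pr)
        h2 = transition_hazard(1, 2.0, [1.0], 2.0, pr)
        assert h2 == pytest.approx(2.0 * h1)

    def test_hand_computed_weibull_value(self):
        # alpha * kappa * lambda * t^(kappa-1) * e^{x beta}
        # = 1 * 2 * 0.5 * 1.5 * 2 = 3.0
        pr = params_of([np.log(2.0)], [0.0], [0.0], [2, 1, 1], [0.5, 0.1, 0.1])
        assert transition_hazard(1, 1.5, [1.0], 1.0, pr) == pytest.approx(3.0)

    def test_domain_errors(self):
        pr = params_of([0.0], [0.0], [0.0], [1, 1, 1], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError):
            transition_hazard(1, 0.0, [0.0], 1.0, pr)
        with pytest.raises(ValueError):
            transition_hazard(4, 1.0, [0.0], 1.0, pr)
        with pytest.raises(ValueError):
            transition_hazard(1, 1.0, [0.0], -1.0, pr)


class TestConditionalLoglik:
    def test_vanishing_rates_give_zero_contribution(self):
        pr = params_of([0.0], [0.0], [0.0], [1, 1, 1], [0.0, 0.0, 0.0])
        s = {"y1": 5.0, "delta1": 0, "y2": 5.0, "delta2": 0, "x": [1.0]}
        assert subject_loglik_conditional(s, 1.0, pr) == pytest.approx(0.0)

    def test_exponential_death_without_illness_hand_value(self):
        # pattern (0,1): log h2(y2) - (H01 + H02)(y2) = log 0.1 - 0.4
        pr = params_of([0.0], [0.0], [0.0], [1, 1, 1], [0.1, 0.1, 0.1])
        s = {"y1": 2.0, "delta1": 0, "y2": 2.0, "delta2": 1, "x": [0.0]}
        expect = np.log(0.1) - 0.4
        assert subject_loglik_conditional(s, 1.0, pr) == pytest.approx(expect)

    def test_full_pattern_matches_density_factorisation(self):
        # (1,1) semi-Markov: log[h1(y1) e^{-alpha A(y1)} h3(s) e^{-alpha H3(s)}]
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=2)
            pr = params_of(
                rng.normal(0, 0.3, 2), rng.normal(0, 0.3, 2), rng.normal(0, 0.3, 2),
                kappa=rng.uniform(0.8, 1.6, 3), lam=rng.uniform(0.05, 0.4, 3),
            )
            alpha = rng.uniform(0.3, 2.5)
            y1, y2 = 1.2, 2.7
            s = y2 - y1
            e1, e2, e3 = (np.exp(x @ b) for b in (pr.beta1, pr.beta2, pr.beta3))
            k, lam = pr.kappa, pr.lam
            h1 = alpha * k[0] * lam[0] * y1 ** (k[0] - 1) * e1
            h3 = alpha * k[2] * lam[2] * s ** (k[2] - 1) * e3
            A = lam[0] * y1 ** k[0] * e1 + lam[1] * y1 ** k[1] * e2
            H3 = lam[2] * s ** k[2] * e3
            expect = np.log(h1) + np.log(h3) - alpha * (A + H3)
            got = subject_loglik_conditional(
                {"y1": y1, "delta1": 1, "y2": y2, "delta2": 1, "x": x}, alpha, pr
            )
            assert got == pytest.approx(expect, abs=1e-12)

    def test_invalid_pattern_rejected(self):
        pr = params_of([0.0], [0.0], [0.0], [1, 1, 1], [0.1, 0.1, 0.1])
        s = {"y1": 1.0, "delta1": 0, "y2": 2.0, "delta2": 1, "x": [0.0]}
        with pytest.raises(ValueError, match="pattern"):
            subject_loglik_conditional(s, 1.0, pr)


class TestMarginalLoglik:
    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            subject, pr = random_subject_and_params(rng)
            cohort = subject_df([subject])
            closed = marginal_loglik(cohort, pr)
            quad = quadrature_marginal_loglik(subject, pr)
            assert abs(closed - quad) < 1e-6

    def test_single_subject_gamma_ratio_hand_formula(self):
        # (1,1) pattern: closed form must equal
        # E + lgamma(1/th + 2) - lgamma(1/th) + 2 log th - (1/th + 2) log(1 + th H)
        pr = params_of([0.2], [0.1], [-0.1], [1.2, 1.0, 0.9],
                       [0.1, 0.2, 0.3], theta=0.7)
        s = {"y1": 1.0, "delta1": 1, "y2": 2.0, "delta2": 1, "x": [1.0]}
        from scipy.special import gammaln

        e1, e2, e3 = np.exp(0.2), np.exp(0.1), np.exp(-0.1)
        H = 0.1 * 1.0 ** 1.2 * e1 + 0.2 * 1.0 ** 1.0 * e2 + 0.3 * 1.0 ** 0.9 * e3
        E = (
            np.log(1.2 * 0.1 * 1.0 ** 0.2 * e1)
            + np.log(0.9 * 0.3 * 1.0 ** (-0.1) * e3)
        )
        th = 0.7
        expect = (
            E + gammaln(1 / th + 2) - gammaln(1 / th) + 2 * np.log(th)
            - (1 / th + 2) * np.log1p(th * H)
        )
        assert marginal_loglik(subject_df([s]), pr) == pytest.approx(expect)

    def test_continuous_at_theta_zero(self):
        cohort, _ = generate_cohort(recovery_config(n=100, seed=2))
        pr = recovery_config(n=100).true_params
        pr0 = dataclasses.replace(pr, theta=0.0)
        pr_eps = dataclasses.replace(pr, theta=1e-10)
        assert abs(marginal_loglik(cohort, pr0) - marginal_loglik(cohort, pr_eps)) < 1e-6

    @pytest.mark.parametrize("clock", ["semi-markov", "markov"])
    def test_theta_zero_equals_independent_weibull_ph(self, clock):
        cohort, _ = generate_cohort(recovery_config(n=60, seed=4, clock=clock))
        pr = dataclasses.replace(
            recovery_config(n=60, clock=clock).true_params, theta=0.0
        )
        assert marginal_loglik(cohort, pr) == pytest.approx(
            naive_weibull_ph_loglik(cohort, pr), abs=1e-8
        )

    def test_negative_theta_rejected(self):
        cohort, _ = generate_cohort(recovery_config(n=20, seed=0))
        with pytest.raises(ValueError):
            dataclasses.replace(recovery_config(n=20).true_params, theta=-1.0)

    def test_clocks_coincide_for_exponential_transition3(self):
        # kappa3 = 1 is memoryless: absolute-time and sojourn clocks agree
        cohort, _ = generate_cohort(recovery_config(n=200, seed=6))
        pr = recovery_config(n=200).true_params
        assert pr.kappa[2] == 1.0
        prm = dataclasses.replace(pr, clock="markov")
        assert marginal_loglik(cohort, pr) == pytest.approx(
            marginal_loglik(cohort, prm), abs=1e-9
        )

    def test_analytic_gradient_matches_finite_differences(self):
        cohort, _ = generate_cohort(recovery_config(n=150, seed=8))
        pr = recovery_config(n=150).true_params
        arrays = _prepare_arrays(cohort, pr)
        vec = _pack(pr, with_theta=True)
        for clock in ("semi-markov", "markov"):
            _, g = _negloglik_and_grad(vec, pr.p, clock, True, *arrays)
            for i in range(len(vec)):
                e = np.zeros_like(vec)
                e[i] = 1e-6
                fp, _ = _negloglik_and_grad(vec + e, pr.p, clock, True, *arrays)
                fm, _ = _negloglik_and_grad(vec - e, pr.p, clock, True, *arrays)
                fd = (fp - fm) / 2e-6
                assert abs(g[i] - fd) / (1 + abs(fd)) < 1e-5


class TestFitMLE:
    def test_loglik_at_optimum_dominates_truth(self):
        cfg = recovery_config(n=1500, seed=12)
        cohort, _ = generate_cohort(cfg)
        fit = fit_mle(cohort, options=FitOptions(n_starts=1, compute_se=False))
        assert fit.converged
        assert fit.loglik >= marginal_loglik(cohort, cfg.true_params)

    def test_parameter_recovery_within_three_se(self):
        cfg = recovery_config(n=4000, seed=0)
        cohort, _ = generate_cohort(cfg)
        fit = fit_mle(cohort)
        tr = cfg.true_params
        for est, se, true in [
            (fit.estimates.beta1, fit.se["beta1"], tr.beta1),
            (fit.estimates.beta2, fit.se["beta2"], tr.beta2),
            (fit.estimates.beta3, fit.se["beta3"], tr.beta3),
        ]:
            assert np.all(np.abs(est - true) < 3 * se)
        assert abs(np.log(fit.estimates.theta) - np.log(tr.theta)) < 3 * float(
            fit.se["log_theta"][0]
        )

    def test_null_effects_covered_by_wald_cis(self):
        # with all beta = 0 the 95% CI should contain HR = 1 at roughly
        # nominal rates per covariate
        n_rep, hits = 50, None
        for seed in range(n_rep):
            cfg = recovery_config(n=2000, seed=100 + seed)
            cfg = dataclasses.replace(
                cfg,
                true_params=dataclasses.replace(
                    cfg.true_params,
                    beta1=np.zeros(3), beta2=np.zeros(3), beta3=np.zeros(3),
                ),
            )
            cohort, _ = generate_cohort(cfg)
            fit = fit_mle(cohort, options=FitOptions(n_starts=1))
            t1 = fit.hr_table[fit.hr_table["transition"] == 1]
            cover = ((t1["ci_low"] <= 1.0) & (1.0 <= t1["ci_high"])).to_numpy()
            hits = cover.astype(int) if hits is None else hits + cover
        assert np.all(hits / n_rep >= 0.9)

    def test_constant_covariate_is_identifiability_error(self):
        cohort, _ = generate_cohort(recovery_config(n=100, seed=1))
        cohort.data["x1"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_mle(cohort)

    def test_deterministic_given_data_and_options(self):
        cohort, _ = generate_cohort(recovery_config(n=400, seed=3))
        f1 = fit_mle(cohort, options=FitOptions(compute_se=False))
        f2 = fit_mle(cohort, options=FitOptions(compute_se=False))
        np.testing.assert_array_equal(f1.estimates.beta1, f2.estimates.beta1)
        assert f1.loglik == f2.loglik

    def test_no_frailty_data_hits_theta_boundary(self):
        cfg = recovery_config(n=1200, seed=5, theta=0.0)
        cohort, _ = generate_cohort(cfg)
        fit = fit_mle(cohort, options=FitOptions(compute_se=False))
        assert fit.estimates.theta < 0.3

    def test_hr_table_brackets_hr(self):
        cohort, _ = generate_cohort(recovery_config(n=800, seed=7))
        fit = fit_mle(cohort)
        t = fit.hr_table
        assert ((t["ci_low"] <= t["hr"]) & (t["hr"] <= t["ci_high"])).all()
        assert np.isfinite(fit.loglik)


class TestCIF:
    PR = IllnessDeathParams(
        [0.4], [0.2], [0.1], kappa=[1.2, 1.1, 1.0],
        lam=[3.5e-5, 4.5e-5, 5.0e-4], theta=1.0,
    )

    def test_zero_horizon_zero_risk(self):
        assert cif_nonterminal([0.0], 0.0, self.PR) == 0.0

    def test_negative_horizon_rejected(self):
        with pytest.raises(ValueError):
            cif_nonterminal([0.0], -1.0, self.PR)

    def test_reduces_to_weibull_cdf_without_death(self):
        pr = params_of([0.3], [0.0], [0.0], [1.4, 1, 1], [1e-4, 0.0, 0.0])
        for t in (200.0, 1000.0, 3000.0):
            expect = 1.0 - np.exp(-1e-4 * t ** 1.4 * np.exp(0.3))
            assert cif_nonterminal([1.0], t, pr) == pytest.approx(expect, abs=1e-9)

    def test_monotone_and_bounded(self):
        ts = np.linspace(0, 4000, 15)
        vals = [cif_nonterminal([0.5], t, self.PR) for t in ts]
        assert np.all(np.diff(vals) >= -1e-12)
        assert all(0.0 <= v <= 1.0 for v in vals)
        # dominated by the no-death, no-frailty onset bound
        pr_free = dataclasses.replace(
            self.PR, theta=0.0, lam=np.array([self.PR.lam[0], 0.0, 0.0])
        )
        for t, v in zip(ts[1:], vals[1:]):
            assert v <= cif_nonterminal([0.5], t, pr_free) + 1e-12

    def test_matches_monte_carlo(self):
        n = 40_000
        x = np.array([1.0])
        X = np.tile(x, (n, 1))
        T1, T2, _ = __import__("semicompete").simulate_illness_death(
            X, self.PR, seed=123
        )
        for t in (500.0, 1500.0):
            emp = np.mean(np.isfinite(T1) & (T1 <= t))
            se = np.sqrt(emp * (1 - emp) / n)
            assert abs(cif_nonterminal(x, t, self.PR) - emp) < 3 * se
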