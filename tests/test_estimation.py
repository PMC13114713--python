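"""Dual-criterion estimator: Wald intervals, admissibility, backward
objective, constrained grid minimization against brute force, the ML
baseline, and Weibull shape recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tailsplit import (
    AdmissibleInterval,
    EstimationError,
    EstimatorConfig,
    GPDParams,
    backward_objective,
    bernoulli_loglik,
    empirical_p,
    estimate_stage,
    estimate_stage_one,
    gpd_condition,
    gpd_sf,
    is_admissible,
    ml_estimate,
    recover_initial,
    wald_interval,
    weibull_estimate_shape,
    weibull_sf,
)


class TestEmpiricalP:
    def test_examples(self):
        assert empirical_p([1, 0, 1, 1]) == 0.75
        assert empirical_p(np.zeros(10)) == 0.0
        with pytest.raises(ValueError):
            empirical_p([])

    def test_matches_independent_tally(self, rng):
        draws = (rng.random(50) < 0.25).astype(int)
        assert empirical_p(draws) == sum(int(d) for d in draws) / 50


class TestWaldInterval:
    def test_printed_example(self):
        iv = wald_interval(0.25, 50, 0.2)
        assert iv.lower == pytest.approx(0.17072, abs=1e-4)
        assert iv.upper == pytest.approx(0.32928, abs=1e-4)

    def test_collapses_as_gamma_goes_to_one(self):
        iv = wald_interval(0.3, 50, 1 - 1e-12)
        assert iv.upper - iv.lower == pytest.approx(0.0, abs=1e-6)

    def test_mirror_symmetry(self):
        a = wald_interval(0.2, 40, 0.2)
        b = wald_interval(0.8, 40, 0.2)
        assert a.lower == pytest.approx(1 - b.upper)
        assert a.upper == pytest.approx(1 - b.lower)

    def test_width_shrinks_as_sqrt_K(self):
        w = lambda K: wald_interval(0.25, K, 0.2).upper - wald_interval(0.25, K, 0.2).lower
        # (K-1) variance denominator: widths scale as sqrt((K1-1)/(K2-1))
        assert w(401) / w(101) == pytest.approx(np.sqrt(100 / 400), rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            wald_interval(0.25, 1, 0.2)
        with pytest.raises(ValueError):
            wald_interval(0.0, 50, 0.2)


class TestAdmissibility:
    def test_full_interval_always_admissible(self):
        assert is_admissible(2.0, 0.3, 5.0, 1.0, AdmissibleInterval(0.0, 1.0))

    def test_unit_case_boundary(self):
        # conditional sf over increment 1 under GPD(1,1) is 0.5
        inside = AdmissibleInterval(0.4, 0.6)
        outside = AdmissibleInterval(0.6, 0.9)
        assert is_admissible(1.0, 1.0, 2.0, 1.0, inside)
        assert not is_admissible(1.0, 1.0, 2.0, 1.0, outside)

    def test_exact_configuration_admissible_for_any_gamma(self, gpd_ref):
        s_prev, s_cur = 2.0, 5.0
        cond = gpd_condition(gpd_ref, s_prev)
        p_exact = gpd_sf(s_cur - s_prev, cond)
        for gamma in [0.01, 0.2, 0.9]:
            iv = wald_interval(p_exact, 50, gamma)
            assert is_admissible(cond.c, cond.a, s_cur, s_prev, iv)


class TestBackwardObjective:
    def test_self_consistent_point_is_zero(self):
        # conditional median of GPD(1, a=1+1*1=2) above s=1 is 2 = 3-1
        assert backward_objective(1.0, 1.0, 3.0, 1.0, 0.5) == pytest.approx(0.0)

    def test_quarter_quantile_value(self):
        # (1+x/2)^-1 = 0.75 => x = 2/3; |2 - 2/3| = 4/3
        assert backward_objective(1.0, 1.0, 3.0, 1.0, 0.75) == pytest.approx(4.0 / 3.0)

    def test_v_shape_in_p_hat(self):
        """|increment - Q(p)| is continuous and piecewise monotone: Q is
        monotone in the level, so the objective decreases to 0 then rises."""
        ps = np.linspace(0.05, 0.95, 181)
        vals = np.array([backward_objective(0.8, 1.5, 4.0, 1.0, p) for p in ps])
        signs = np.sign(np.diff(vals))
        changes = np.count_nonzero(np.diff(signs[signs != 0]))
        assert changes <= 1
        # continuity: refining the grid shrinks the largest jump
        ps2 = np.linspace(0.05, 0.95, 361)
        vals2 = np.array([backward_objective(0.8, 1.5, 4.0, 1.0, p) for p in ps2])
        assert np.max(np.abs(np.diff(vals2))) < 0.75 * np.max(np.abs(np.diff(vals)))


class TestEstimateStage:
    def test_matches_brute_force_enumeration(self, gpd_ref):
        """The vectorized constrained minimizer equals exhaustive search."""
        s_jm2, s_jm1, s_j = 0.0, 3.8, 13.0
        p_hat_prev, interval = 0.22, AdmissibleInterval(0.15, 0.35)
        cfg = EstimatorConfig(grid_size=20, refine=False)
        got, got_obj = estimate_stage(s_jm2, s_jm1, s_j, p_hat_prev, interval, cfg)

        best = None
        c_grid = np.geomspace(0.05, 5.0, 20)
        a_grid = np.geomspace(0.05, 20.0, 20)
        for c in c_grid:
            for a in a_grid:
                cond = gpd_condition(GPDParams(c, a), s_jm1)
                if not interval.contains(gpd_sf(s_j - s_jm1, cond)):
                    continue
                obj = backward_objective(c, a, s_jm1, s_jm2, p_hat_prev)
                key = (obj, c, a)
                if best is None or key < best:
                    best = key
        assert best is not None
        assert got_obj == pytest.approx(best[0], rel=1e-12)
        assert (got.c, got.a) == (pytest.approx(best[1]), pytest.approx(best[2]))

    def test_full_interval_reduces_to_unconstrained(self):
        cfg = EstimatorConfig(grid_size=30, refine=False)
        iv = AdmissibleInterval(0.0, 1.0)
        params, obj = estimate_stage(0.0, 3.8, 13.0, 0.25, iv, cfg)
        cc, aa = cfg.grid()
        all_obj = backward_objective(cc, aa, 3.8, 0.0, 0.25)
        assert obj == pytest.approx(all_obj.min(), rel=1e-12)

    def test_self_consistent_grid_point_returned(self):
        # put the true point on the grid; exact conditionals make objective 0
        true = GPDParams(1.0, 1.0)
        s1, s2, s3 = 1.0, 3.0, 7.0  # p=0.5 ladder of GPD(1,1)
        cfg = EstimatorConfig(search_box=(0.5, 2.0, 0.5, 2.0), grid_size=5,
                              refine=False)
        iv = wald_interval(0.5, 50, 0.2)
        params, obj = estimate_stage(s1, s2, s3, 0.5, iv, cfg)
        assert obj == pytest.approx(0.0, abs=1e-12)
        assert (params.c, params.a) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_empty_admissible_set_raises(self):
        cfg = EstimatorConfig(grid_size=10, fallback_halve_gamma=False)
        iv = AdmissibleInterval(0.999, 0.9999)  # no candidate puts mass there
        with pytest.raises(EstimationError):
            estimate_stage(0.0, 3.8, 300.0, 0.25, iv, cfg)

    def test_gamma_widening_fallback(self):
        cfg = EstimatorConfig(grid_size=40, refine=False)
        narrow = wald_interval(0.25, 100000, 0.2)  # very tight interval
        # widening path requires the stage data to recompute the interval
        params, _ = estimate_stage(0.0, 3.8, 13.0, 0.25, narrow, cfg,
                                   gamma=0.2, p_hat_j=0.25, K=50)
        cond = gpd_condition(params, 3.8)
        wide = wald_interval(0.25, 50, 0.1)
        assert wide.contains(gpd_sf(13.0 - 3.8, cond))


class TestBernoulliLoglik:
    def test_direct_sum(self):
        outcomes = np.r_[np.ones(60), np.zeros(140)]
        assert bernoulli_loglik(0.3, outcomes) == pytest.approx(
            60 * np.log(0.3) + 140 * np.log(0.7)
        )

    def test_maximized_at_empirical_mean(self, rng):
        outcomes = (rng.random(200) < 0.3).astype(int)
        p_hat = outcomes.mean()
        grid = np.linspace(0.01, 0.99, 99)
        lls = bernoulli_loglik(grid, outcomes)
        assert abs(grid[np.argmax(lls)] - p_hat) <= 0.011

    def test_boundary_sentinel(self):
        assert bernoulli_loglik(0.0, [1, 0]) == -np.inf
        assert bernoulli_loglik(1.0, [1, 0]) == -np.inf

    def test_likelihood_plateau_spans_tail_index_range(self, gpd_ref, rng):
        """One Bernoulli level leaves (c, a) nearly unidentified: the
        within-1-unit-of-max region spans at least half the c range."""
        s1 = 3.8089
        pi_true = gpd_sf(s1, gpd_ref)
        outcomes = (rng.random(200) < pi_true).astype(int)
        cfg = EstimatorConfig(grid_size=60)
        cc, aa = cfg.grid()
        pis = np.power(1.0 + cc * s1 / aa, -1.0 / cc)
        lls = bernoulli_loglik(pis, outcomes)
        near_max = cc[lls >= lls.max() - 1.0]
        c_lo, c_hi = cfg.search_box[0], cfg.search_box[1]
        assert near_max.max() / near_max.min() >= np.sqrt(c_hi / c_lo)


class TestMLBaseline:
    def test_recovers_probability_scale(self, gpd_ref):
        """With exact stage counts the cumulative ML fit reproduces the
        observed exceedance probabilities at every stage."""
        ladder = [0.0, 3.8089, 13.0, 44.0]
        counts = []
        for s_prev, s_cur in zip(ladder[:-1], ladder[1:]):
            p = gpd_sf(s_cur, gpd_ref) / gpd_sf(s_prev, gpd_ref)
            counts.append((int(round(1000 * p)), 1000))
        fit = ml_estimate(ladder, counts, EstimatorConfig(grid_size=80))
        for (n_exc, K), s_prev, s_cur in zip(counts, ladder[:-1], ladder[1:]):
            cond = gpd_condition(fit, s_prev)
            assert gpd_sf(s_cur - s_prev, cond) == pytest.approx(
                n_exc / K, abs=0.05
            )


class TestRecoverInitial:
    def test_inverse_of_conditioning(self):
        assert recover_initial(GPDParams(0.8, 9.5), 10.0) == GPDParams(0.8, 1.5)
        theta = GPDParams(1.3, 2.2)
        assert recover_initial(gpd_condition(theta, 6.5), 6.5).a == pytest.approx(2.2)

    def test_identity_at_zero(self):
        theta = GPDParams(0.8, 1.5)
        assert recover_initial(theta, 0.0) == theta

    def test_nonpositive_scale_flagged(self):
        with pytest.raises(ValueError):
            recover_initial(GPDParams(2.0, 1.0), 1.0)


class TestWeibullShape:
    @pytest.mark.parametrize("shape", [0.6, 1.0, 2.3])
    def test_exact_conditionals_recover_shape(self, shape, weibull_ref):
        from tailsplit import WeibullParams, weibull_quantile

        params = WeibullParams(2.0, shape)
        p = 0.25
        ladder = [0.0] + [weibull_quantile(1 - p**j, params) for j in range(1, 5)]
        log_pc = [float(np.log(weibull_sf(s2, params) / weibull_sf(s1, params)))
                  if s1 > 0 else float(np.log(weibull_sf(s2, params)))
                  for s1, s2 in zip(ladder[:-1], ladder[1:])]
        got = weibull_estimate_shape(ladder, log_pc)
        assert got == pytest.approx(shape, abs=1e-6)

    def test_equal_increment_geometry_returns_one(self):
        ladder = [0.0, 1.0, 2.0, 3.0]
        log_pc = [np.log(0.25)] * 3
        assert weibull_estimate_shape(ladder, log_pc) == pytest.approx(1.0, abs=1e-6)

    def test_noisy_recovery_over_replicas(self):
        """K=50 binomial noise on the stage probabilities still localizes
        the shape on average."""
        from tailsplit import WeibullParams, weibull_quantile

        params = WeibullParams(2.0, 1.5)
        p = 0.25
        ladder = [0.0] + [weibull_quantile(1 - p**j, params) for j in range(1, 5)]
        exact = [weibull_sf(s2, params) / max(weibull_sf(s1, params), 1e-300)
                 for s1, s2 in zip(ladder[:-1], ladder[1:])]
        rng = np.random.default_rng(7)
        shapes = []
        for _ in range(200):
            p_hats = np.clip(rng.binomial(50, exact) / 50, 1e-3, 1 - 1e-3)
            shapes.append(weibull_estimate_shape(ladder, np.log(p_hats).tolist()))
        assert np.mean(shapes) == pytest.approx(1.5, abs=0.25)
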