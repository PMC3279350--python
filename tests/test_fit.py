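import numpy as np
import pytest

from burrowmap import (
    CovariateTerm,
    DistanceCovariate,
    Interaction,
    ModelSpec,
    MSHCParams,
    MultiTypeStraussModel,
    TypedPointPattern,
    adapt_h_to_pattern,
    aicc,
    akaike_weights,
    make_quadrature,
    monte_carlo_lr_test,
    pl_ratio,
    simulate_mshc,
)


@pytest.fixture
def empty_pattern(unit_window):
    return TypedPointPattern(unit_window, [], [], np.array([], dtype=object))


class TestQuadrature:
    def test_uniform_tiling_empty_pattern(self, unit_window, empty_pattern):
        quad = make_quadrature(empty_pattern, unit_window, 10.0, types=["K", "A"])
        for t in ("K", "A"):
            sel = quad.types == t
            assert sel.sum() == 100
            assert np.allclose(quad.weights[sel], 100.0)

    def test_weights_sum_to_window_area_per_type(self, csr_pattern):
        quad = make_quadrature(csr_pattern, csr_pattern.window, 7.3)
        for t in ("K", "A"):
            total = quad.weights[quad.types == t].sum()
            assert total == pytest.approx(csr_pattern.window.area, rel=1e-9)

    def test_counting_weight_shared_tile(self, unit_window):
        # one data point in the same tile as its dummy node: each gets half
        pat = TypedPointPattern(unit_window, [5.0], [5.0],
                                np.array(["K"], dtype=object))
        quad = make_quadrature(pat, unit_window, 10.0)
        sel = (quad.types == "K") & (quad.x < 10) & (quad.y < 10)
        assert sel.sum() == 2
        assert np.allclose(quad.weights[sel], 50.0)

    def test_bad_spacing_rejected(self, unit_window, empty_pattern):
        with pytest.raises(ValueError):
            make_quadrature(empty_pattern, unit_window, 0.0)
        with pytest.raises(ValueError):
            make_quadrature(empty_pattern, unit_window, 150.0)


class TestPoissonSpecialCase:
    def test_csr_mple_recovers_closed_form(self, csr_pattern):
        """Poisson spec: beta_hat = n/|W| exactly, logPL = closed form."""
        spec = ModelSpec(("K", "A"), ())
        res = MultiTypeStraussModel(csr_pattern, spec, dummy_spacing=10,
                                    edge_correction="none").fit({})
        area = csr_pattern.window.area
        assert np.exp(res.params.log_beta["K"]) == pytest.approx(20 / area, rel=1e-8)
        assert np.exp(res.params.log_beta["A"]) == pytest.approx(30 / area, rel=1e-8)
        closed = 20 * np.log(20 / area) + 30 * np.log(30 / area) - 50
        assert res.logpl == pytest.approx(closed, rel=1e-10)
        assert res.converged

    def test_refining_dummy_grid_converges(self, csr_pattern):
        """For the interacting model the quadrature error shrinks with the
        dummy spacing; successive refinements agree."""
        spec = ModelSpec.reduced(("K", "A"))
        h_r = {("K", "K"): (2.0, 10.0), ("A", "A"): (2.0, 10.0)}
        vals = []
        for spacing in (20.0, 10.0, 5.0, 2.5):
            res = MultiTypeStraussModel(csr_pattern, spec, dummy_spacing=spacing,
                                        edge_correction="none").fit(h_r)
            vals.append(res.logpl)
        assert abs(vals[-1] - vals[-2]) < abs(vals[1] - vals[0]) + 1.0
        assert abs(vals[-1] - vals[-2]) < 2.0


class TestInteractionFitting:
    def test_gamma_recovery_simulated(self, unit_window):
        """MPLE at the true (h, r) recovers log gamma_KA over replicates:
        positive association is detected nearly always and the median
        estimate lands near the truth."""
        truth = MSHCParams(
            ("K", "A"), {"K": np.log(0.004), "A": np.log(0.004)},
            interactions={("K", "K"): Interaction(2.0, 8.0, 0.6),
                          ("A", "A"): Interaction(2.0, 8.0, 0.6),
                          ("K", "A"): Interaction(1.0, 5.0, 3.0)})
        spec = ModelSpec.full(("K", "A"))
        h_r = {("K", "K"): (2, 8), ("A", "A"): (2, 8), ("K", "A"): (1, 5)}
        gammas = []
        for seed in range(25):
            sim = simulate_mshc(truth, unit_window, n_steps=30_000, seed=seed)
            res = MultiTypeStraussModel(sim, spec, dummy_spacing=5,
                                        edge_correction="none").fit(
                adapt_h_to_pattern(sim, h_r))
            gammas.append(res.params.interaction("K", "A").gamma)
        gammas = np.asarray(gammas)
        assert np.mean(gammas > 1) >= 0.95
        assert abs(np.log(np.median(gammas)) - np.log(3.0)) < 0.5 * np.log(3.0)

    def test_degenerate_interaction_column_dropped(self, unit_window):
        """A gamma term with no pairs in range is dropped; the fit equals the
        reduced model's."""
        pat = TypedPointPattern(unit_window, [10.0, 90.0], [10.0, 90.0],
                                np.array(["K", "A"], dtype=object))
        full = ModelSpec.full(("K", "A"))
        with pytest.warns(UserWarning, match="no pairs in range"):
            res = MultiTypeStraussModel(pat, full, dummy_spacing=20,
                                        edge_correction="none").fit(
                {("K", "K"): (0.0, 5.0), ("A", "A"): (0.0, 5.0),
                 ("K", "A"): (0.0, 5.0)})
        assert ("A", "K") in res.dropped_terms or ("K", "K") in res.dropped_terms

    def test_hard_core_violation_flagged_infeasible(self, unit_window):
        pat = TypedPointPattern(unit_window, [10.0, 12.0], [10.0, 10.0],
                                np.array(["K", "A"], dtype=object))
        full = ModelSpec(("K", "A"), (("K", "A"),))
        res = MultiTypeStraussModel(pat, full, dummy_spacing=20,
                                    edge_correction="none").fit(
            {("K", "A"): (3.0, 8.0)})
        assert res.logpl == -np.inf and not res.converged

    def test_covariate_coefficient_recovery(self, unit_window):
        """A strong distance covariate effect is recovered with the right
        sign and rough magnitude."""
        refs = np.array([[25.0, 25.0], [75.0, 75.0], [25.0, 75.0], [75.0, 25.0]])
        cov = {"dist_ref": DistanceCovariate(refs)}
        truth = MSHCParams(("A",), {"A": np.log(0.02)},
                           covariates={"dist_ref": {"A": -0.15}})
        spec = ModelSpec(("A",), (), (CovariateTerm("dist_ref", ("A",)),))
        coefs = []
        for seed in range(10):
            sim = simulate_mshc(truth, unit_window, covariates=cov,
                                n_steps=30_000, seed=seed)
            res = MultiTypeStraussModel(sim, spec, covariates=cov,
                                        dummy_spacing=4,
                                        edge_correction="none").fit({})
            coefs.append(res.params.covariates["dist_ref"]["A"])
        assert np.median(coefs) == pytest.approx(-0.15, abs=0.06)
        assert np.mean(np.asarray(coefs) < 0) >= 0.9

    def test_nesting_logpl_monotone(self, unit_window):
        """logPL(full) >= logPL(reduced) on any dataset."""
        truth = MSHCParams(("K", "A"),
                           {"K": np.log(0.003), "A": np.log(0.003)})
        h_r_red = {("K", "K"): (1, 6), ("A", "A"): (1, 6)}
        h_r_full = {**h_r_red, ("K", "A"): (1, 6)}
        for seed in range(5):
            sim = simulate_mshc(truth, unit_window, n_steps=10_000, seed=seed)
            kw = dict(dummy_spacing=8, edge_correction="none")
            red = MultiTypeStraussModel(sim, ModelSpec.reduced(("K", "A")),
                                        **kw).fit(adapt_h_to_pattern(sim, h_r_red))
            ful = MultiTypeStraussModel(sim, ModelSpec.full(("K", "A")),
                                        **kw).fit(adapt_h_to_pattern(sim, h_r_full))
            assert ful.logpl >= red.logpl - 1e-6


class TestProfile:
    def test_single_point_grid(self, csr_pattern):
        spec = ModelSpec(("K", "A"), (("K", "A"),))
        m = MultiTypeStraussModel(csr_pattern, spec, dummy_spacing=10,
                                  edge_correction="none")
        res = m.fit_profile(("K", "A"), [1.0], [5.0])
        assert res.profile.best == (1.0, 5.0)
        assert len(res.profile.grid) == 1

    def test_adding_grid_points_never_lowers_maximum(self, csr_pattern):
        spec = ModelSpec(("K", "A"), (("K", "A"),))
        m = MultiTypeStraussModel(csr_pattern, spec, dummy_spacing=10,
                                  edge_correction="none")
        small = m.fit_profile(("K", "A"), [0.5], [4.0, 8.0])
        large = m.fit_profile(("K", "A"), [0.5], [4.0, 8.0, 12.0])
        assert large.profile.best_logpl >= small.profile.best_logpl - 1e-9

    def test_profile_recovers_interaction_range(self, unit_window):
        """The profiled r lands within one grid step of the generating value
        in most replicates."""
        truth = MSHCParams(
            ("K", "A"), {"K": np.log(0.004), "A": np.log(0.004)},
            interactions={("K", "A"): Interaction(1.0, 6.0, 3.0),
                          ("K", "K"): Interaction(2.0, 8.0, 0.6),
                          ("A", "A"): Interaction(2.0, 8.0, 0.6)})
        spec = ModelSpec.full(("K", "A"))
        base = {("K", "K"): (2.0, 8.0), ("A", "A"): (2.0, 8.0)}
        hits = 0
        n_rep = 12
        for seed in range(n_rep):
            sim = simulate_mshc(truth, unit_window, n_steps=30_000, seed=100 + seed)
            m = MultiTypeStraussModel(sim, spec, dummy_spacing=6,
                                      edge_correction="none")
            hmin = min(1.0, 0.999 * float(
                np.min(np.hypot(*(sim.coords("K")[:, None, :]
                                  - sim.coords("A")[None, :, :]).transpose(2, 0, 1)))))
            res = m.fit_profile(("K", "A"), [hmin], [2.0, 4.0, 6.0, 8.0, 10.0],
                                h_r_fixed=base)
            if abs(res.profile.best[1] - 6.0) <= 2.0:
                hits += 1
        assert hits >= 0.7 * n_rep


class TestInformationCriteria:
    def test_aicc_values(self):
        assert aicc(0.0, 0, 10) == 0.0
        assert aicc(-5.0, 2, 10) == pytest.approx(10 + 4 + 12 / 7)
        # large-n limit reduces to plain AIC
        assert aicc(-81.7, 4, 10**9) == pytest.approx(171.4, abs=1e-3)
        with pytest.raises(ValueError):
            aicc(-5.0, 4, 5)

    def test_akaike_weights(self):
        w = akaike_weights([3469.0, 3489.4])
        assert w[0] == pytest.approx(1.0, abs=5e-5)
        assert w[1] == pytest.approx(0.0, abs=5e-5)
        assert np.allclose(akaike_weights([10.0, 10.0]), [0.5, 0.5])
        w3 = akaike_weights([0.0, 2.0, 4.0])
        expected = np.array([1, np.e**-1, np.e**-2])
        assert np.allclose(w3, expected / expected.sum())
        assert w3.sum() == pytest.approx(1.0)

    def test_pl_ratio_identities(self):
        assert pl_ratio(-1755.5, -1780.7) == pytest.approx(50.4)
        assert pl_ratio(-1477.3, -1498.1) == pytest.approx(41.6)
        assert pl_ratio(-10.0, -10.0) == 0.0
        with pytest.warns(UserWarning, match="negative"):
            pl_ratio(-11.0, -10.0)


class TestMonteCarloLRTest:
    def test_delta_obs_consistent_with_pl_ratio(self, unit_window):
        truth = MSHCParams(("K", "A"), {"K": np.log(0.003), "A": np.log(0.003)},
                           interactions={("K", "K"): Interaction(2, 8, 0.5),
                                         ("A", "A"): Interaction(2, 8, 0.5)})
        data = simulate_mshc(truth, unit_window, n_steps=10_000, seed=11)
        h_r_red = {("K", "K"): (2, 8), ("A", "A"): (2, 8)}
        h_r_full = {**h_r_red, ("K", "A"): (0.5, 5.0)}
        res = monte_carlo_lr_test(
            data, ModelSpec.reduced(("K", "A")), ModelSpec.full(("K", "A")),
            h_r_red, h_r_full, nsim=19, seed=4, sim_steps=4_000,
            edge_correction="none")
        assert res.delta_obs == pytest.approx(
            pl_ratio(res.full_fit, res.reduced_fit))
        assert 0.0 < res.p_value <= 1.0
        assert len(res.delta_sims) + res.n_failed == 19

    def test_requires_nested_specs(self, csr_pattern):
        with pytest.raises(ValueError):
            monte_carlo_lr_test(
                csr_pattern, ModelSpec.full(("K", "A")),
                ModelSpec.reduced(("K", "A")), {}, {}, nsim=19)
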