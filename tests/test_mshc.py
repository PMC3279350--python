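import numpy as np
import pytest
from scipy.stats import chisquare, kstest, poisson

from burrowmap import (
    DistanceCovariate,
    Interaction,
    ModelSpec,
    MSHCParams,
    TypedPointPattern,
    conditional_intensity,
    nn_distance,
    pair_count,
    pairwise_distance_matrix,
    simulate_conditional_on_n,
    simulate_mshc,
)


@pytest.fixture
def two_type_params():
    return MSHCParams(
        ("K", "A"),
        {"K": np.log(0.003), "A": np.log(0.003)},
        interactions={("K", "A"): Interaction(1.0, 5.0, 3.0)},
    )


class TestParams:
    def test_interaction_validation(self):
        with pytest.raises(ValueError):
            Interaction(5.0, 5.0, 1.0)
        with pytest.raises(ValueError):
            Interaction(1.0, 5.0, -0.1)

    def test_pair_symmetry_and_serialization(self, two_type_params, tmp_path):
        p = two_type_params
        assert p.interaction("A", "K") is p.interaction("K", "A")
        path = tmp_path / "params.yaml"
        p.to_yaml(path)
        back = MSHCParams.from_file(path)
        assert back.interaction("K", "A").gamma == 3.0
        assert back.log_beta == p.log_beta

    def test_model_spec_nesting(self):
        red = ModelSpec.reduced(("K", "A"))
        full = ModelSpec.full(("K", "A"))
        assert red.is_nested_in(full)
        assert not full.is_nested_in(red)
        assert ("A", "K") in full.pairs and ("A", "K") not in red.pairs


class TestPairCount:
    def test_interval_count(self, unit_window):
        pat = TypedPointPattern(unit_window, [0.5, 3.0, 7.0], [0, 0, 0],
                                np.array(["A"] * 3, dtype=object))
        t = pair_count((0.0, 0.0), "K", pat, ("K", "A"), 1.0, 5.0)
        assert t == 1   # only d = 3 falls in (1, 5]

    def test_no_opposing_points(self, unit_window):
        pat = TypedPointPattern(unit_window, [1.0], [1.0],
                                np.array(["K"], dtype=object))
        assert pair_count((0, 0), "K", pat, ("K", "A"), 1, 5) == 0

    def test_matches_brute_force(self, unit_window):
        rng = np.random.default_rng(21)
        pat = TypedPointPattern(unit_window, rng.uniform(0, 100, 50),
                                rng.uniform(0, 100, 50),
                                np.array(["K"] * 25 + ["A"] * 25, dtype=object))
        u = (50.0, 50.0)
        t = pair_count(u, "K", pat, ("K", "A"), 2.0, 20.0)
        d = np.hypot(pat.coords("A")[:, 0] - u[0], pat.coords("A")[:, 1] - u[1])
        assert t == int(np.sum((d > 2.0) & (d <= 20.0)))


class TestConditionalIntensity:
    def test_reduces_to_beta_without_neighbours(self, unit_window, two_type_params):
        pat = TypedPointPattern(unit_window, [90.0], [90.0],
                                np.array(["A"], dtype=object))
        lam = conditional_intensity((10.0, 10.0), "K", pat, two_type_params)
        assert lam == pytest.approx(0.003)

    def test_single_neighbour_in_annulus(self, unit_window):
        params = MSHCParams(("K", "A"), {"K": np.log(0.01), "A": np.log(0.01)},
                            interactions={("K", "A"): Interaction(1, 5, 3.0)})
        pat = TypedPointPattern(unit_window, [14.0], [10.0],
                                np.array(["A"], dtype=object))
        lam = conditional_intensity((10.0, 10.0), "K", pat, params)
        assert lam == pytest.approx(0.03)

    def test_hard_core_gives_zero(self, unit_window, two_type_params):
        pat = TypedPointPattern(unit_window, [10.5], [10.0],
                                np.array(["A"], dtype=object))
        assert conditional_intensity((10.0, 10.0), "K", pat, two_type_params) == 0.0

    def test_gamma_zero_limit(self, unit_window):
        params = MSHCParams(("K", "A"), {"K": 0.0, "A": 0.0},
                            interactions={("K", "A"): Interaction(1, 5, 0.0)})
        pat = TypedPointPattern(unit_window, [13.0], [10.0],
                                np.array(["A"], dtype=object))
        assert conditional_intensity((10.0, 10.0), "K", pat, params) == 0.0

    def test_log_linear_in_pair_count(self, unit_window):
        """Doubling t_KA multiplies lambda by gamma^2."""
        params = MSHCParams(("K", "A"), {"K": np.log(0.01), "A": np.log(0.01)},
                            interactions={("K", "A"): Interaction(1, 5, 3.0)})
        one = TypedPointPattern(unit_window, [13.0], [10.0],
                                np.array(["A"], dtype=object))
        two = TypedPointPattern(unit_window, [13.0, 7.0], [10.0, 10.0],
                                np.array(["A", "A"], dtype=object))
        l1 = conditional_intensity((10.0, 10.0), "K", one, params)
        l2 = conditional_intensity((10.0, 10.0), "K", two, params)
        assert l2 == pytest.approx(l1 * 3.0)

    def test_covariate_enters_log_linearly(self, unit_window):
        params = MSHCParams(("K",), {"K": np.log(0.01)},
                            covariates={"dist": {"K": -0.2}})
        cov = {"dist": DistanceCovariate([(0.0, 0.0)])}
        pat = TypedPointPattern(unit_window, [90.0], [90.0],
                                np.array(["K"], dtype=object))
        lam = conditional_intensity((3.0, 4.0), "K", pat, params, cov)
        assert lam == pytest.approx(0.01 * np.exp(-0.2 * 5.0))


class TestSimulation:
    def test_poisson_limit_count_distribution(self, unit_window):
        """gamma = 1, no covariates: counts follow Poisson(beta |W|)."""
        mean = 30.0
        params = MSHCParams(("A",), {"A": np.log(mean / unit_window.area)})
        counts = np.array([
            simulate_mshc(params, unit_window, n_steps=20_000, seed=1000 + i).n
            for i in range(200)
        ])
        se = np.sqrt(mean / 200)
        assert abs(counts.mean() - mean) < 3 * np.sqrt(counts.var() / 200)
        assert abs(counts.mean() - mean) < 3 * se * 2
        disp = counts.var(ddof=1) / counts.mean()
        assert 0.75 < disp < 1.3
        # chi-square GOF against Poisson(30), pooled tails
        edges = [0, 22, 26, 29, 32, 36, np.inf]
        obs = np.histogram(counts, bins=edges)[0]
        cdf = poisson(mean).cdf
        probs = np.diff([0] + [cdf(e - 1) if np.isfinite(e) else 1.0 for e in edges[1:]])
        stat, p = chisquare(obs, probs * 200, ddof=0, sum_check=False)
        assert p > 0.01

    def test_hard_core_never_violated(self, unit_window):
        params = MSHCParams(
            ("K", "A"), {"K": np.log(0.004), "A": np.log(0.004)},
            interactions={("K", "K"): Interaction(10.0, 12.0, 1.0),
                          ("K", "A"): Interaction(3.0, 8.0, 2.0)})
        for seed in range(5):
            pat = simulate_mshc(params, unit_window, n_steps=30_000, seed=seed)
            dkk = pairwise_distance_matrix(pat, "K", "K")
            np.fill_diagonal(dkk, np.inf)
            if dkk.size:
                assert dkk.min() > 10.0
            dka = pairwise_distance_matrix(pat, "K", "A")
            if dka.size:
                assert dka.min() > 3.0

    def test_fixed_seed_determinism(self, unit_window, two_type_params):
        a = simulate_mshc(two_type_params, unit_window, n_steps=10_000, seed=5)
        b = simulate_mshc(two_type_params, unit_window, n_steps=10_000, seed=5)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert (a.types == b.types).all()

    def test_attraction_shrinks_cross_distances(self, unit_window):
        """gamma_KA > 1 draws colonies toward mounds relative to gamma = 1.

        Intraspecific hard cores (as in the study system) keep the mutually
        attractive two-type model from degenerate pile-up."""
        base = {"K": np.log(0.002), "A": np.log(0.002)}
        intra = {("K", "K"): Interaction(8.0, 10.0, 1.0),
                 ("A", "A"): Interaction(4.0, 5.0, 1.0)}
        means = {}
        for gamma in (1.0, 4.0):
            params = MSHCParams(("K", "A"), base,
                                interactions={**intra,
                                              ("K", "A"): Interaction(0.5, 6.0, gamma)})
            vals = []
            for seed in range(15):
                pat = simulate_mshc(params, unit_window, n_steps=20_000, seed=seed)
                d = nn_distance(pat, "A", "K")
                if d.size:
                    vals.append(d.mean())
            means[gamma] = np.mean(vals)
        assert means[4.0] < means[1.0]

    def test_capacity_guard_raises(self, unit_window):
        # gamma > 1 same-type interaction in a bounded window with high beta:
        # clustering blows the pattern up against the safety cap
        params = MSHCParams(("A",), {"A": np.log(0.05)},
                            interactions={("A", "A"): Interaction(0.1, 30.0, 1.5)})
        with pytest.raises(RuntimeError, match="capacity"):
            simulate_mshc(params, unit_window, n_steps=200_000, seed=0,
                          capacity=600)


class TestConditionalOnN:
    def test_counts_and_hard_cores(self, unit_window):
        params = MSHCParams(("K", "A"), {"K": 0.0, "A": 0.0},
                            interactions={("K", "K"): Interaction(8.0, 10.0, 1.0)})
        pat = simulate_conditional_on_n(params, unit_window,
                                        {"K": 12, "A": 20}, seed=3,
                                        n_steps=20_000)
        assert pat.n_by_type() == {"A": 20, "K": 12}
        d = pairwise_distance_matrix(pat, "K", "K")
        np.fill_diagonal(d, np.inf)
        assert d.min() > 8.0

    def test_single_point_uniform_marginals(self, unit_window):
        """n = 1, gamma = 1: the stationary location is uniform."""
        params = MSHCParams(("A",), {"A": 0.0})
        xs = []
        for seed in range(200):
            pat = simulate_conditional_on_n(params, unit_window, {"A": 1},
                                            seed=seed, n_steps=300)
            xs.append(pat.x[0])
        assert kstest(np.asarray(xs) / 100.0, "uniform").pvalue > 0.01

    def test_determinism(self, unit_window):
        params = MSHCParams(("A",), {"A": 0.0},
                            interactions={("A", "A"): Interaction(2.0, 4.0, 0.5)})
        a = simulate_conditional_on_n(params, unit_window, {"A": 15}, seed=9,
                                      n_steps=5_000)
        b = simulate_conditional_on_n(params, unit_window, {"A": 15}, seed=9,
                                      n_steps=5_000)
        assert np.array_equal(a.x, b.x)

    def test_infeasible_packing_raises(self):
        from burrowmap import Window

        small = Window(0, 20, 0, 20)
        params = MSHCParams(("K",), {"K": 0.0},
                            interactions={("K", "K"): Interaction(15.0, 16.0, 1.0)})
        with pytest.raises(RuntimeError, match="packing"):
            simulate_conditional_on_n(params, small, {"K": 10}, seed=0)
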