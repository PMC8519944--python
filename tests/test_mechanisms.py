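import numpy as np
import pytest
from scipy import stats

from mechnet import (DEFAULT_PARAMETER_RANGES, MechanismSpec, default_weights,
                     distance_matrix, grow_network, simulate_dd, simulate_er,
                     simulate_mechanism, simulate_nm, simulate_pa, simulate_sw)

from oracles import naive_dd, naive_niche, uniform_attachment_max_degree

ALL_SPECS = [
    ("ER", 0.3, True), ("ER", 0.3, False),
    ("DD", 0.5, False), ("DD", 0.5, True),
    ("NM", 0.15, True),
    ("PA", 2.0, True), ("PA", 2.0, False),
    ("SW", 0.2, False), ("SW", 0.2, True),
]


@pytest.mark.parametrize("mechanism,param,directed", ALL_SPECS)
def test_simulator_output_invariants(mechanism, param, directed):
    """Square binary adjacency, zero diagonal, symmetry iff undirected,
    bit-identical replay under the same seed."""
    spec = MechanismSpec(mechanism, param, directed=directed)
    net = simulate_mechanism(spec, 20, np.random.default_rng(7))
    a = net.adjacency
    assert a.shape == (20, 20)
    assert net.is_binary()
    assert np.all(np.diag(a) == 0)
    if not directed:
        assert np.array_equal(a, a.T)
    replay = simulate_mechanism(spec, 20, np.random.default_rng(7))
    assert np.array_equal(a, replay.adjacency)


class TestER:
    def test_extreme_probabilities(self):
        assert simulate_er(5, 1.0, directed=True).n_edges == 20
        assert simulate_er(5, 0.0).n_edges == 0

    def test_realized_density_is_binomial(self, rng):
        net = simulate_er(200, 0.3, directed=True, rng=rng)
        trials = 200 * 199
        density = net.n_edges / trials
        sd = np.sqrt(0.3 * 0.7 / trials)
        assert abs(density - 0.3) < 3 * sd

    def test_replicate_mean_density_matches_p(self, rng):
        reps = 500
        dens = [simulate_er(30, 0.2, rng=rng).n_edges / (30 * 29 / 2)
                for _ in range(reps)]
        se = np.std(dens, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(dens) - 0.2) < 4 * se

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            simulate_er(10, 1.2)
        with pytest.raises(ValueError):
            simulate_er(1, 0.5)


class TestPA:
    def test_single_edge_per_arrival_gives_tree(self, rng):
        net = simulate_pa(30, 1.7, m=1, rng=rng)
        assert net.n_edges == 29

    def test_uniform_attachment_limit(self, rng):
        """power=0 reduces to uniform attachment: max-degree distribution
        matches an independent uniform-attachment oracle."""
        impl = [simulate_pa(100, 0.0, m=1, rng=rng).adjacency.sum(axis=1).max()
                for _ in range(200)]
        oracle = [uniform_attachment_max_degree(100, rng) for _ in range(200)]
        assert stats.ks_2samp(impl, oracle).pvalue > 0.01
        assert np.mean(impl) < 50  # far below the 99-degree star

    def test_high_power_concentrates_degree(self, rng):
        hub = [simulate_pa(100, 4.0, m=1, rng=rng).adjacency.sum(axis=1).max()
               for _ in range(200)]
        flat = [simulate_pa(100, 0.0, m=1, rng=rng).adjacency.sum(axis=1).max()
                for _ in range(200)]
        assert np.median(hub) > np.median(flat)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            simulate_pa(5, 1.0, m=5)
        with pytest.raises(ValueError):
            simulate_pa(5, -1.0)


class TestDD:
    def test_no_divergence_duplicates_everything(self, rng):
        # copying with no deletions from a complete seed keeps the graph complete
        net = simulate_dd(10, 0.0, rng=rng)
        assert net.n_edges == 10 * 9 // 2

    def test_full_divergence_gives_tree(self, rng):
        net = simulate_dd(10, 1.0, rng=rng)
        deg = net.adjacency.sum(axis=1)
        assert net.n_edges == 9
        assert np.all(deg >= 1)

    def test_mean_degree_self_consistent(self, rng):
        reps = 300
        impl = [simulate_dd(50, 0.5, rng=rng).adjacency.sum(axis=1).mean()
                for _ in range(reps)]
        oracle = [naive_dd(50, 0.5, rng).sum(axis=1).mean() for _ in range(reps)]
        se = np.sqrt(np.var(impl, ddof=1) / reps + np.var(oracle, ddof=1) / reps)
        assert abs(np.mean(impl) - np.mean(oracle)) < 4 * se

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            simulate_dd(10, 1.5)


class TestNM:
    def test_prey_sets_are_contiguous_niche_intervals(self, rng):
        for _ in range(20):
            net, (eta, _r, _c) = simulate_nm(30, 0.15, rng=rng, return_params=True)
            order = np.argsort(eta)
            for row in net.adjacency[:, order]:
                prey = np.flatnonzero(row)
                # contiguous up to the dropped self-loop position
                assert len(prey) == 0 or prey[-1] - prey[0] <= len(prey)

    def test_mean_connectance_matches_oracle(self, rng):
        reps = 200
        impl = [simulate_nm(50, 0.1, rng=rng).n_edges / (50 * 49) for _ in range(reps)]
        oracle = [naive_niche(50, 0.1, rng)[0].sum() / (50 * 49) for _ in range(reps)]
        se_i = np.std(impl, ddof=1) / np.sqrt(reps)
        se_o = np.std(oracle, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(impl) - 0.1) < 3 * (se_i + 0.005)  # small no-cannibalism bias
        assert abs(np.mean(impl) - np.mean(oracle)) < 4 * np.hypot(se_i, se_o)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            simulate_nm(10, 0.5)


class TestSW:
    def test_unrewired_lattice_is_circulant(self):
        net = simulate_sw(20, 0.0, k=2)
        deg = net.adjacency.sum(axis=1)
        assert np.all(deg == 4)
        # enumeration oracle: triangles / connected triples of C20(1,2)
        a = net.adjacency
        triangles = np.trace(a @ a @ a) / 6
        triples = sum(d * (d - 1) / 2 for d in deg)
        assert triangles == 20
        assert 3 * triangles / triples == 0.5

    @pytest.mark.parametrize("rewire_p", [0.0, 0.3, 1.0])
    def test_edge_count_is_preserved(self, rewire_p, rng):
        assert simulate_sw(25, rewire_p, k=2, rng=rng).n_edges == 50

    def test_fully_rewired_matches_degree_matched_random(self, rng):
        """transitivity at rewire_p=1 is that of a degree-matched random graph."""
        import networkx as nx
        impl, oracle = [], []
        for _ in range(200):
            net = simulate_sw(100, 1.0, k=2, rng=rng)
            g = nx.from_numpy_array(net.adjacency)
            impl.append(nx.transitivity(g))
            degseq = [int(d) for d in net.adjacency.sum(axis=1)]
            cm = nx.configuration_model(degseq, seed=int(rng.integers(2 ** 31)))
            oracle.append(nx.transitivity(nx.Graph(cm)))
        se = np.hypot(np.std(impl, ddof=1), np.std(oracle, ddof=1)) / np.sqrt(200)
        assert abs(np.mean(impl) - np.mean(oracle)) < 4 * se

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            simulate_sw(4, 0.1, k=2)


class TestDispatchAndGrowth:
    def test_dispatch_delegates(self, rng):
        net = simulate_mechanism(MechanismSpec("ER", 0.99, directed=False,
                                               parameter_range=(0, 1)), 4, rng)
        assert net.n_edges <= 6
        complete = simulate_mechanism(MechanismSpec("ER", 1.0, parameter_range=(0, 1),
                                                    directed=True), 4, rng)
        assert complete.n_edges == 12
        lattice = simulate_mechanism(MechanismSpec("SW", 0.0, parameter_range=(0, 1)),
                                     20, rng)
        assert np.all(lattice.adjacency.sum(axis=1) == 4)

    def test_nm_is_directed_only(self, rng):
        with pytest.raises(ValueError):
            simulate_mechanism(MechanismSpec("NM", 0.1, directed=False), 10, rng)

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValueError):
            MechanismSpec("XX", 0.5)

    def test_parameter_outside_range_rejected(self):
        with pytest.raises(ValueError):
            MechanismSpec("ER", 1.5)

    def test_grown_er_with_zero_probability_is_empty(self, rng):
        spec = MechanismSpec("ER", 0.0, directed=True, parameter_range=(0, 1))
        net = grow_network(spec, 15, rng)
        assert net.n_edges <= 1  # only the 2-node growth seed

    def test_grown_pa_is_canonical_pa(self):
        """PA is inherently a growth process: the standardized growth form
        delegates to the canonical simulator."""
        spec = MechanismSpec("PA", 1.0, directed=False)
        grown = grow_network(spec, 40, np.random.default_rng(5))
        canon = simulate_pa(40, 1.0, m=1, rng=np.random.default_rng(5))
        assert np.array_equal(grown.adjacency, canon.adjacency)

    def test_grown_er_differs_from_canonical_er(self, rng):
        """Growth imposes structure: grown and canonical ER families are
        farther apart than networks within either family."""
        spec = MechanismSpec("ER", 0.2, directed=True)
        grown = [grow_network(spec, 20, rng) for _ in range(12)]
        canon = [simulate_er(20, 0.2, directed=True, rng=rng) for _ in range(12)]
        w = default_weights()
        D = distance_matrix(grown + canon, weights=w)
        within = np.r_[D[:12, :12][np.triu_indices(12, 1)],
                       D[12:, 12:][np.triu_indices(12, 1)]]
        between = D[:12, 12:].ravel()
        assert between.mean() > within.mean()
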