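import copy

import numpy as np
import pytest

from mechnet import (MechanismSpec, StackWeights, StateSpace, build_state_space,
                     calibrate_weights, component_distance, default_weights,
                     network_distance, ordinate, property_profile,
                     simulate_mechanism, simulate_pa, simulate_sw)
from mechnet.properties import COMPONENT_NAMES
from mechnet.state_space import calibration_panel, distance_matrix


def profile_pair_differing_in(component, delta, rng):
    """Two profiles of the same network, one with ``component`` shifted."""
    net = simulate_sw(12, 0.2, rng=rng)
    a = property_profile(net)
    b = copy.deepcopy(a)
    b.components[component] = b.components[component] + delta
    return a, b


class TestComponentDistance:
    def test_identical_profiles_are_at_zero(self, rng):
        p = property_profile(simulate_sw(12, 0.2, rng=rng))
        assert all(component_distance(p, p, c) == 0 for c in COMPONENT_NAMES)

    def test_scalar_absolute_difference(self, rng):
        a, b = profile_pair_differing_in("transitivity", 0.75, rng)
        assert component_distance(a, b, "transitivity") == pytest.approx(0.75)

    def test_vector_euclidean_distance(self, rng):
        a, b = profile_pair_differing_in("in_degree", 0.0, rng)
        b.components["in_degree"] = np.array([2.0, 1.0, 1.0])
        a.components["in_degree"] = np.array([2.0, 2.0, 2.0])
        assert component_distance(a, b, "in_degree") == pytest.approx(np.sqrt(2))

    def test_shorter_vector_is_zero_padded(self, rng):
        a, b = profile_pair_differing_in("in_degree", 0.0, rng)
        a.components["in_degree"] = np.array([3.0, 1.0])
        b.components["in_degree"] = np.array([3.0])
        assert component_distance(a, b, "in_degree") == pytest.approx(1.0)

    def test_unknown_component_rejected(self, rng):
        p = property_profile(simulate_sw(12, 0.2, rng=rng))
        with pytest.raises(ValueError):
            component_distance(p, p, "nope")


class TestNetworkDistance:
    def test_pseudometric_properties(self, rng):
        x = simulate_sw(15, 0.2, rng=rng)
        y = simulate_pa(15, 2.0, rng=rng)
        w = default_weights()
        assert network_distance(x, x, w) == 0.0
        assert network_distance(x, y, w) == pytest.approx(network_distance(y, x, w))
        assert network_distance(x, y, w) >= 0

    def test_uniform_weighted_average(self, uniform_weights, rng):
        a, b = profile_pair_differing_in("transitivity", 0.9, rng)
        d = sum(uniform_weights.weights[i] * component_distance(a, b, c)
                for i, c in enumerate(COMPONENT_NAMES))
        assert d == pytest.approx(0.9 / 18)

    def test_invariant_under_relabeling(self, rng):
        x = simulate_sw(15, 0.2, rng=rng)
        y = simulate_pa(15, 2.0, rng=rng)
        w = default_weights()
        d0 = network_distance(x, y, w)
        assert network_distance(x.relabeled(rng.permutation(15)),
                                y.relabeled(rng.permutation(15)),
                                w) == pytest.approx(d0, abs=1e-9)


class TestStackWeights:
    def test_validation(self):
        with pytest.raises(ValueError):
            StackWeights(np.ones(18))  # does not sum to 1
        with pytest.raises(ValueError):
            StackWeights(np.full(17, 1 / 17))

    def test_shipped_default_is_valid(self):
        w = default_weights()
        assert np.all(w.weights >= 0)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_json_roundtrip(self, tmp_path):
        w = default_weights()
        w.save(tmp_path / "w.json")
        again = StackWeights.load(tmp_path / "w.json")
        assert np.array_equal(w.weights, again.weights)


class TestCalibration:
    def test_small_panel_rejected(self, rng):
        with pytest.raises(ValueError):
            calibrate_weights([simulate_sw(10, 0.2, rng=rng)] * 2)

    def test_weights_sum_to_one_and_nonnegative(self, rng):
        panel = calibration_panel(n_networks=30, n_nodes=12, seed=3)
        w = calibrate_weights(panel)
        assert np.all(w.weights >= 0)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_component_gets_zero_weight(self, rng):
        nets = [simulate_sw(12, 0.3, rng=rng) for _ in range(10)]
        profiles = [property_profile(n) for n in nets]
        for p in profiles:  # force one component constant across the panel
            p.components["community_count"] = 2.0
        w = calibrate_weights(profiles)
        assert w.weights[COMPONENT_NAMES.index("community_count")] == 0.0

    def test_loadings_match_eigendecomposition_oracle(self, rng):
        """PC1 loadings agree (up to sign) with an independent z-score +
        covariance-eigendecomposition oracle."""
        panel = [property_profile(n)
                 for n in calibration_panel(n_networks=50, n_nodes=12, seed=9)]
        w = calibrate_weights(panel)
        n = len(panel)
        X = np.array([[component_distance(panel[i], panel[j], c)
                       for c in COMPONENT_NAMES]
                      for i in range(n) for j in range(i + 1, n)])
        sd = X.std(axis=0)
        Z = np.where(sd > 0, (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1), 0.0)
        vals, vecs = np.linalg.eigh(np.cov(Z, rowvar=False))
        expected = np.abs(vecs[:, -1])
        expected[sd == 0] = 0.0
        assert np.allclose(w.weights, expected / expected.sum(), atol=1e-8)

    def test_reproducible(self):
        w1 = calibrate_weights(calibration_panel(20, 12, seed=5))
        w2 = calibrate_weights(calibration_panel(20, 12, seed=5))
        assert np.array_equal(w1.weights, w2.weights)


class TestStateSpace:
    def test_identical_networks_give_zero_matrix(self, rng):
        net = simulate_sw(12, 0.2, rng=rng)
        space = build_state_space([net, net.copy()])
        assert np.array_equal(space.D, np.zeros((2, 2)))

    def test_matrix_matches_pairwise_calls(self, rng):
        nets = [simulate_sw(12, 0.2, rng=rng), simulate_pa(12, 2.0, rng=rng),
                simulate_pa(12, 0.5, rng=rng)]
        w = default_weights()
        space = build_state_space(nets, weights=w)
        assert np.allclose(space.D, space.D.T)
        assert np.all(np.diag(space.D) == 0)
        for i in range(3):
            for j in range(i + 1, 3):
                assert space.D[i, j] == pytest.approx(
                    network_distance(nets[i], nets[j], w), abs=1e-9)

    def test_mechanisms_separate_in_state_space(self, rng):
        pa = [simulate_pa(20, 3.0, rng=rng) for _ in range(10)]
        sw = [simulate_sw(20, 0.1, rng=rng) for _ in range(10)]
        D = distance_matrix(pa + sw, weights=default_weights())
        iu = np.triu_indices(10, 1)
        within = np.r_[D[:10, :10][iu], D[10:, 10:][iu]]
        between = D[:10, 10:].ravel()
        assert between.mean() > within.mean()


class TestOrdination:
    def test_equidistant_triple_embeds_as_equilateral_triangle(self):
        D = np.full((3, 3), 1.0) - np.eye(3)
        space = StateSpace(profiles=[], weights=StackWeights.uniform(), D=D)
        coords, stress = ordinate(space, seed=0)
        d01 = np.linalg.norm(coords[0] - coords[1])
        d02 = np.linalg.norm(coords[0] - coords[2])
        d12 = np.linalg.norm(coords[1] - coords[2])
        assert max(d01, d02, d12) - min(d01, d02, d12) < 1e-3

    def test_degenerate_space_rejected(self):
        space = StateSpace(profiles=[], weights=StackWeights.uniform(),
                           D=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            ordinate(space)

    def test_seeded_and_reproducible(self, rng):
        nets = [simulate_mechanism(MechanismSpec("SW", p, directed=False), 15, rng)
                for p in (0.05, 0.2, 0.5, 0.9)]
        space = build_state_space(nets)
        c1, s1 = ordinate(space, seed=11)
        c2, s2 = ordinate(space, seed=11)
        assert np.array_equal(c1, c2) and s1 == s2
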