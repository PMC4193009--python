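"""Integration, strength, clustering, density — against brute-force
oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dynconn as dc
from dynconn.metrics import (
    clustering_coefficient,
    integration,
    network_density,
    node_strength,
)


# ------------------------------------------------------------- oracles
def strength_oracle(E):
    n = len(E)
    k = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                k[i] += E[i, j]
    return k


def clustering_oracle(E, degree_kind="binary"):
    """Direct double-loop evaluation of the cube-root triangle formula."""
    n = len(E)
    W = E.copy().astype(float)
    np.fill_diagonal(W, 0.0)
    W[W < 0] = 0.0
    if W.max() > 0:
        W = W / W.max()
    C = np.zeros(n)
    for i in range(n):
        deg = sum(1 for j in range(n) if W[i, j] > 0)
        if deg < 2:
            continue
        num = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    num += (W[i, j] * W[i, h] * W[j, h]) ** (1 / 3)
        k = deg if degree_kind == "binary" else W[i].sum()
        if k * (k - 1) > 0:
            C[i] = num / (k * (k - 1))
    return C


def _random_symmetric(rng, n, density=0.6, signed=False):
    A = rng.uniform(0, 1, size=(n, n))
    A *= rng.uniform(size=(n, n)) < density
    if signed:
        A *= rng.choice([-1.0, 1.0], size=(n, n))
    A = np.triu(A, 1)
    return A + A.T


class TestIntegration:
    def test_identity_zero_both_modes(self):
        assert integration(np.eye(5), "marrelec", input_kind="covariance") == 0
        assert integration(np.eye(5), "literal", input_kind="covariance") == 0

    def test_closed_form_2x2(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        got = integration(R, "marrelec", input_kind="covariance")
        assert got == pytest.approx(-0.5 * np.log(1 - 0.36), abs=1e-4)
        assert got == pytest.approx(0.2231, abs=1e-4)

    def test_literal_mode_is_sign_flipped_on_correlations(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        m = integration(R, "marrelec", input_kind="covariance")
        l = integration(R, "literal", input_kind="covariance")
        assert l == pytest.approx(-m, abs=1e-12)

    def test_block_additivity(self, rng):
        A = rng.standard_normal((30, 3))
        B = rng.standard_normal((30, 4))
        Sa, Sb = np.cov(A.T), np.cov(B.T)
        S = np.block([[Sa, np.zeros((3, 4))], [np.zeros((4, 3)), Sb]])
        tot = integration(S, input_kind="covariance")
        parts = (integration(Sa, input_kind="covariance")
                 + integration(Sb, input_kind="covariance"))
        assert tot == pytest.approx(parts, abs=1e-10)

    def test_variance_rescaling_invariance(self, rng):
        A = rng.standard_normal((40, 5))
        S = np.cov(A.T)
        d = np.diag(rng.uniform(0.5, 3.0, 5))
        assert integration(d @ S @ d, input_kind="covariance") == pytest.approx(
            integration(S, input_kind="covariance"), abs=1e-10
        )

    def test_fisher_z_input(self):
        Z = np.arctanh(np.array([[0.0, 0.6], [0.6, 0.0]]))
        np.fill_diagonal(Z, 0.0)
        cm = dc.ConditionMatrix("s", "before", Z)
        assert integration(cm) == pytest.approx(0.2231, abs=1e-4)

    def test_nonnegative_marrelec(self, rng):
        for _ in range(20):
            A = rng.standard_normal((30, 6))
            assert integration(np.cov(A.T), input_kind="covariance") >= 0


class TestNodeStrength:
    def test_triangle_example(self):
        E = np.zeros((3, 3))
        E[0, 1] = E[1, 0] = 0.5
        E[0, 2] = E[2, 0] = 0.5
        np.testing.assert_allclose(node_strength(E), [1.0, 0.5, 0.5])

    def test_zero_graph(self):
        np.testing.assert_array_equal(node_strength(np.zeros((4, 4))), 0.0)

    @given(st.integers(2, 8), st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True)
    def test_matches_loop_oracle_signed(self, n, seed):
        E = _random_symmetric(np.random.default_rng(seed), n, signed=True)
        np.testing.assert_allclose(node_strength(E), strength_oracle(E),
                                   atol=1e-12)


class TestClustering:
    def test_binary_triangle(self):
        E = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(clustering_coefficient(E), 1.0)

    def test_path_has_no_triangles(self):
        E = np.zeros((3, 3))
        E[0, 1] = E[1, 0] = 1.0
        E[1, 2] = E[2, 1] = 1.0
        np.testing.assert_allclose(clustering_coefficient(E), 0.0)

    def test_weighted_triangle_hand_value(self):
        # edges (1,2)=1, (1,3)=1, (2,3)=0.125: the node joining the two
        # unit edges has C = 2 * 0.125^(1/3) / (2*1) = 0.5
        E = np.zeros((3, 3))
        E[0, 1] = E[1, 0] = 1.0
        E[0, 2] = E[2, 0] = 1.0
        E[1, 2] = E[2, 1] = 0.125
        C = clustering_coefficient(E)
        assert C[0] == pytest.approx(0.5, abs=1e-12)

    @given(st.integers(3, 8), st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True)
    def test_matches_loop_oracle(self, n, seed):
        E = _random_symmetric(np.random.default_rng(seed), n)
        np.testing.assert_allclose(clustering_coefficient(E),
                                   clustering_oracle(E), atol=1e-10)

    @given(st.integers(3, 8), st.integers(0, 10_000))
    @settings(max_examples=20, derandomize=True)
    def test_strength_denominator_matches_oracle(self, n, seed):
        E = _random_symmetric(np.random.default_rng(seed), n)
        np.testing.assert_allclose(
            clustering_coefficient(E, degree_kind="strength"),
            clustering_oracle(E, degree_kind="strength"),
            atol=1e-10,
        )

    def test_binary_reduces_to_unweighted_coefficient(self, rng):
        """On 0/1 graphs the formula equals the classic triangle count
        ratio (networkx oracle)."""
        import networkx as nx

        for seed in range(10):
            g = nx.gnp_random_graph(8, 0.5, seed=seed)
            E = nx.to_numpy_array(g)
            expected = np.array([nx.clustering(g)[i] for i in range(8)])
            np.testing.assert_allclose(clustering_coefficient(E), expected,
                                       atol=1e-12)

    def test_values_in_unit_interval(self, rng):
        for _ in range(20):
            E = _random_symmetric(rng, 7)
            C = clustering_coefficient(E)
            assert np.all((C >= 0) & (C <= 1 + 1e-12))

    def test_permutation_equivariance(self, rng):
        E = _random_symmetric(rng, 6)
        perm = rng.permutation(6)
        P = E[np.ix_(perm, perm)]
        np.testing.assert_allclose(clustering_coefficient(P),
                                   clustering_coefficient(E)[perm],
                                   atol=1e-12)
        np.testing.assert_allclose(node_strength(P),
                                   node_strength(E)[perm], atol=1e-12)


class TestDensity:
    @pytest.mark.parametrize(
        "edges,nodes,expected",
        [(0, 14, 0.0), (91, 14, 1.0), (13, 14, 13 / 91)],
    )
    def test_values(self, edges, nodes, expected):
        assert network_density(edges, nodes) == pytest.approx(expected,
                                                              abs=1e-10)

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            network_density(0, 1)
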