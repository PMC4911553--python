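"""Kernel construction against naive loop oracles and hand computations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metgp import (
    MODEL_TERMS,
    MarkerMatrix,
    Pedigree,
    EnvCovariateTable,
    additive_relationship,
    build_kernel_set,
    env_kernel,
    expand_to_observations,
    genomic_relationship,
    interaction_kernel,
)
from metgp.kernels import assert_valid_kernel


def loop_g_uncentered(X, p):
    n = X.shape[0]
    G = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            G[j, k] = sum(X[j, m] * X[k, m] for m in range(X.shape[1])) / p
    return G


class TestGenomicRelationship:
    def test_centered_hand_example(self):
        mk = MarkerMatrix(["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        G = genomic_relationship(mk, center=True)
        np.testing.assert_allclose(G, [[0.25, -0.25], [-0.25, 0.25]])

    def test_uncentered_matches_loop_oracle(self, rng):
        X = rng.integers(0, 2, size=(20, 100)).astype(float)
        mk = MarkerMatrix([f"l{i}" for i in range(20)], X)
        G = genomic_relationship(mk, center=False)
        np.testing.assert_allclose(G, loop_g_uncentered(X, 100), atol=1e-12)

    def test_centered_matches_loop_oracle(self, rng):
        X = rng.integers(0, 3, size=(15, 40)).astype(float)
        mk = MarkerMatrix([f"l{i}" for i in range(15)], X)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(
            genomic_relationship(mk, center=True), loop_g_uncentered(Xc, 40), atol=1e-12
        )

    def test_vanraden_denominator(self, rng):
        X = rng.integers(0, 3, size=(12, 30)).astype(float)
        mk = MarkerMatrix([f"l{i}" for i in range(12)], X)
        p = X.mean(axis=0) / 2
        denom = 2 * np.sum(p * (1 - p))
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(
            genomic_relationship(mk, scale_mode="vanraden"), Xc @ Xc.T / denom, atol=1e-12
        )

    def test_symmetric_trace_nonnegative(self, rng):
        X = rng.random((10, 25))
        G = genomic_relationship(MarkerMatrix([f"l{i}" for i in range(10)], X))
        assert np.allclose(G, G.T)
        assert np.trace(G) >= 0

    def test_errors(self):
        with pytest.raises(ValueError, match="zero markers"):
            genomic_relationship(MarkerMatrix(["a", "b"], np.zeros((2, 0))))
        mk = MarkerMatrix(["a", "b"], np.ones((2, 3)))
        with pytest.raises(ValueError, match="scale_mode"):
            genomic_relationship(mk, scale_mode="bogus")


def kinship_oracle(pedigree):
    """Recursive coancestry oracle, an independent path to A = 2·kinship."""
    parents = {i: (p1, p2) for i, p1, p2 in pedigree.records}
    order = {ind: k for k, ind in enumerate(pedigree.topological_order())}
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(a, b):
        if a is None or b is None:
            return 0.0
        if order[a] < order[b]:
            a, b = b, a
        fa, ma = parents[a]
        if a == b:
            return 0.5 * (1.0 + f(fa, ma))
        return 0.5 * (f(fa, b) + f(ma, b))

    ids = pedigree.ids
    return ids, np.array([[2.0 * f(i, j) for j in ids] for i in ids])


class TestAdditiveRelationship:
    def test_unrelated_founders_identity(self):
        ids, A = additive_relationship(Pedigree([("a", None, None), ("b", None, None)]))
        np.testing.assert_allclose(A, np.eye(2))

    def test_trio(self):
        ids, A = additive_relationship(
            Pedigree([("f", None, None), ("m", None, None), ("o", "f", "m")])
        )
        i = {x: k for k, x in enumerate(ids)}
        assert A[i["o"], i["o"]] == 1.0
        assert A[i["o"], i["f"]] == 0.5
        assert A[i["f"], i["m"]] == 0.0

    def test_full_sibs(self):
        ids, A = additive_relationship(
            Pedigree([("f", None, None), ("m", None, None),
                      ("s1", "f", "m"), ("s2", "f", "m")])
        )
        i = {x: k for k, x in enumerate(ids)}
        assert A[i["s1"], i["s2"]] == 0.5

    def test_matches_recursive_kinship_oracle(self):
        from metgp import simulate_pedigree

        ped = simulate_pedigree(8, 3, 2, seed=3)
        ids, A = additive_relationship(ped)
        oids, Ao = kinship_oracle(ped)
        order = [oids.index(i) for i in ids]
        np.testing.assert_allclose(A, Ao[np.ix_(order, order)], atol=1e-12)

    def test_cycle_error(self):
        with pytest.raises(ValueError, match="cycle"):
            additive_relationship(Pedigree([("a", "b", None), ("b", "a", None)]))


class TestEnvKernel:
    def test_identity_product(self):
        t = EnvCovariateTable(["s1", "s2"], np.eye(2))
        np.testing.assert_allclose(env_kernel(t, standardize=False), 0.5 * np.eye(2))

    def test_identical_rows_perfect_similarity(self):
        t = EnvCovariateTable(["s1", "s2"], np.array([[1.0, 3.0], [1.0, 3.0]]))
        Om = env_kernel(t, standardize=False)
        assert Om[0, 0] == Om[0, 1] == Om[1, 1]

    def test_loop_oracle(self, rng):
        W = rng.normal(size=(5, 5))
        t = EnvCovariateTable([f"s{i}" for i in range(5)], W)
        Om = env_kernel(t, standardize=False)
        loop = np.array([[sum(W[i, q] * W[j, q] for q in range(5)) / 5
                          for j in range(5)] for i in range(5)])
        np.testing.assert_allclose(Om, loop, atol=1e-12)

    def test_standardized_two_sites(self):
        t = EnvCovariateTable(["s1", "s2"], np.array([[3.0], [7.0]]))
        W = t.values
        z = (W - W.mean(0)) / W.std(0)
        np.testing.assert_allclose(np.abs(z), 1.0)
        Om = env_kernel(t, standardize=True)
        np.testing.assert_allclose(Om, [[1.0, -1.0], [-1.0, 1.0]])

    def test_constant_column_error(self):
        t = EnvCovariateTable(["s1", "s2"], np.array([[1.0, 2.0], [1.0, 5.0]]),
                              ["const_ec", "ok"])
        with pytest.raises(ValueError, match="const_ec"):
            env_kernel(t, standardize=True)


class TestExpansionAndInteraction:
    def test_expand_two_plots_one_line(self):
        K = np.eye(1)
        np.testing.assert_allclose(
            expand_to_observations(K, np.array([0, 0])), np.ones((2, 2))
        )

    def test_expand_loop_oracle(self, rng):
        K = rng.normal(size=(4, 4))
        K = K @ K.T
        idx = rng.integers(0, 4, size=12)
        Ko = expand_to_observations(K, idx)
        loop = np.array([[K[idx[r], idx[s]] for s in range(12)] for r in range(12)])
        np.testing.assert_allclose(Ko, loop, atol=1e-12)

    def test_expand_unmapped_error(self):
        with pytest.raises(ValueError, match="no kernel level"):
            expand_to_observations(np.eye(2), np.array([0, 5]))

    def test_hadamard_identities(self, rng):
        K = rng.normal(size=(5, 5))
        K = K @ K.T
        np.testing.assert_allclose(interaction_kernel(K, np.ones((5, 5))), K)
        np.testing.assert_allclose(
            interaction_kernel(K, np.eye(5)), np.diag(np.diag(K))
        )
        with pytest.raises(ValueError, match="mismatch"):
            interaction_kernel(K, np.eye(4))

    def test_ge_hand_evaluation(self):
        # 4 observations: lines (a,b) × sites (1,2); G for the two lines
        G = np.array([[1.0, 0.3], [0.3, 1.0]])
        line_idx = np.array([0, 1, 0, 1])
        site_idx = np.array([0, 0, 1, 1])
        GE = interaction_kernel(
            expand_to_observations(G, line_idx),
            expand_to_observations(np.eye(2), site_idx),
        )
        expected = np.array([
            [1.0, 0.3, 0.0, 0.0],
            [0.3, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.3],
            [0.0, 0.0, 0.3, 1.0],
        ])
        np.testing.assert_allclose(GE, expected)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 6), st.integers(2, 5))
    def test_hadamard_psd_property(self, seed, n_lines, n_sites):
        """Schur product of two expanded PSD kernels stays symmetric PSD."""
        r = np.random.default_rng(seed)
        K1 = r.normal(size=(n_lines, n_lines + 1))
        K1 = K1 @ K1.T
        li = r.integers(0, n_lines, size=2 * n_lines)
        si = r.integers(0, n_sites, size=2 * n_lines)
        K = interaction_kernel(
            expand_to_observations(K1, li),
            expand_to_observations(np.eye(n_sites), si),
        )
        assert_valid_kernel(K, "GE")


@pytest.fixture(scope="module")
def tiny_inputs(small_bundle):
    bundle, _ = small_bundle
    rows = bundle.phenotypes.df.index[:60]
    pheno = bundle.phenotypes.subset(bundle.phenotypes.df.index.isin(rows))
    return bundle, pheno


class TestBuildKernelSet:
    @pytest.mark.parametrize("model,expected", sorted(MODEL_TERMS.items()))
    def test_model_contents_and_validity(self, tiny_inputs, model, expected):
        bundle, pheno = tiny_inputs
        ks = build_kernel_set(model, pheno, bundle.markers, bundle.pedigree,
                              bundle.env_covariates, validate=True)
        assert tuple(ks.term_names) == expected

    def test_unknown_model_lists_names(self, tiny_inputs):
        bundle, pheno = tiny_inputs
        with pytest.raises(ValueError) as err:
            build_kernel_set("E+G+Z", pheno, bundle.markers)
        for name in MODEL_TERMS:
            assert name in str(err.value)

    def test_missing_component_errors(self, tiny_inputs):
        bundle, pheno = tiny_inputs
        with pytest.raises(ValueError, match="covariable"):
            build_kernel_set("E+W+G", pheno, None, None, None)
        with pytest.raises(ValueError, match="marker"):
            build_kernel_set("E+W+G", pheno, None, None, bundle.env_covariates)
        with pytest.raises(ValueError, match="pedigree"):
            build_kernel_set("E+W+A", pheno, None, None, bundle.env_covariates)

    def test_ge_matches_explicit_hadamard(self, tiny_inputs):
        bundle, pheno = tiny_inputs
        ks = build_kernel_set("E+W+G+GE", pheno, bundle.markers,
                              env_covariates=bundle.env_covariates, validate=False)
        GE = ks.kernels["GE"].matrix
        had = interaction_kernel(ks.kernels["G"].matrix, ks.kernels["E"].matrix)
        np.testing.assert_allclose(GE, had, atol=1e-10)

    def test_line_order_invariance(self, tiny_inputs):
        bundle, pheno = tiny_inputs
        ks1 = build_kernel_set("E+W+G", pheno, bundle.markers,
                               env_covariates=bundle.env_covariates, validate=False)
        perm = np.random.default_rng(0).permutation(bundle.markers.n_lines)
        mk2 = MarkerMatrix([bundle.markers.line_ids[i] for i in perm],
                           bundle.markers.codes[perm])
        ks2 = build_kernel_set("E+W+G", pheno, mk2,
                               env_covariates=bundle.env_covariates, validate=False)
        np.testing.assert_allclose(ks1.kernels["G"].matrix, ks2.kernels["G"].matrix,
                                   atol=1e-10)
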