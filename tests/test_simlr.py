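"""Multikernel similarity learning: kernels, simplex projection,
alternating minimization invariants, cluster-number estimation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import fcbiotype as fb
from fcbiotype.simlr import (
    DEFAULT_K_LIST,
    DEFAULT_SIGMA_LIST,
    KernelBank,
    learn_similarity,
)


def block_similarity(sizes, value=0.5):
    N = sum(sizes)
    S = np.zeros((N, N))
    start = 0
    for s in sizes:
        S[start:start + s, start:start + s] = value
        start += s
    return S


class TestKernels:
    def test_default_grid_has_55_kernels(self):
        X = np.random.default_rng(0).normal(size=(60, 5))
        bank = fb.build_kernels(X)
        assert bank.M == len(DEFAULT_K_LIST) * len(DEFAULT_SIGMA_LIST) == 55

    def test_identical_subjects_full_similarity(self):
        X = np.random.default_rng(1).normal(size=(10, 4))
        X[3] = X[7]
        bank = fb.build_kernels(X)
        assert bank.kernels[0][3, 7] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(np.diagonal(bank.kernels, axis1=1, axis2=2), 1.0)

    def test_kernels_symmetric_nonnegative(self):
        X = np.random.default_rng(2).normal(size=(30, 6))
        bank = fb.build_kernels(X)
        assert np.all(bank.kernels >= 0)
        assert np.allclose(bank.kernels, bank.kernels.transpose(0, 2, 1))

    def test_two_blobs_block_structure(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (25, 8)), rng.normal(6, 1, (25, 8))])
        K = fb.build_kernels(X).average()
        within = (K[:25, :25].mean() + K[25:, 25:].mean()) / 2
        between = K[:25, 25:].mean()
        assert between < within


class TestSimplexProjection:
    def test_already_on_simplex_unchanged(self):
        v = np.array([0.3, 0.3, 0.4])
        np.testing.assert_allclose(fb.project_simplex(v), v, atol=1e-12)

    def test_kkt_closed_form(self):
        np.testing.assert_allclose(fb.project_simplex([2.0, 0.0]), [1.0, 0.0], atol=1e-12)

    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=20))
    @settings(deadline=None)
    def test_contract(self, v):
        out = fb.project_simplex(np.asarray(v))
        assert np.all(out >= 0)
        assert np.sum(out) == pytest.approx(1.0, abs=1e-9)

    def test_projection_is_nearest_point(self):
        """Cross-check against a generic QP solve on random inputs."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(4)
        for _ in range(5):
            v = rng.normal(size=6)
            ours = fb.project_simplex(v)
            res = minimize(
                lambda x: 0.5 * np.sum((x - v) ** 2),
                np.full(6, 1 / 6),
                constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1}],
                bounds=[(0, None)] * 6,
                method="SLSQP",
            )
            np.testing.assert_allclose(ours, res.x, atol=1e-6)


class TestLearnSimilarity:
    def _random_bank(self, seed, N=40):
        X = np.random.default_rng(seed).normal(size=(N, 6))
        return fb.build_kernels(fb.standardize(X))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariants_after_learning(self, seed):
        learned = learn_similarity(self._random_bank(seed), C=3)
        np.testing.assert_allclose(learned.S.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(learned.S >= 0)
        assert learned.w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(learned.w >= 0)
        np.testing.assert_allclose(
            learned.L.T @ learned.L, np.eye(learned.C), atol=1e-8
        )

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_objective_monotone_nonincreasing(self, seed):
        learned = learn_similarity(self._random_bank(seed), C=4)
        tr = np.asarray(learned.objective_trace)
        slack = 1e-9 * np.maximum(np.abs(tr[:-1]), 1.0)
        assert np.all(np.diff(tr) <= slack)

    def test_identical_kernels_give_uniform_weights(self):
        K = block_similarity([10, 10], 0.8) + 0.2 * np.eye(20)
        bank = KernelBank(np.repeat(K[None], 5, axis=0), [(10, 1.0)] * 5)
        learned = learn_similarity(bank, C=2)
        np.testing.assert_allclose(learned.w, 0.2, atol=1e-9)

    def test_block_kernel_recovers_block_structure(self):
        K = block_similarity([12, 12, 12], 0.9)
        np.fill_diagonal(K, 1.0)
        bank = KernelBank(K[None], [(5, 1.0)])
        learned = learn_similarity(bank, C=3)
        S = learned.symmetric()
        off = S.copy()
        off[:12, :12] = off[12:24, 12:24] = off[24:, 24:] = 0
        assert off.max() < 1e-9  # no similarity mass leaks between blocks
        assert fb.estimate_k(S) == 3


class TestEstimateK:
    @pytest.mark.parametrize("b", range(2, 9))
    def test_exact_on_block_diagonals(self, b):
        sizes = [6 + (i % 3) for i in range(b)]
        assert fb.estimate_k(block_similarity(sizes)) == b

    def test_degenerate_returns_min_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fb.estimate_k(np.full((20, 20), 0.5)) == 2

    def test_tie_break_toward_smaller_k(self):
        """Two disjoint 2-node blocks tuned so the Laplacian spectrum is
        {0, 0, 0.5, 1}: the gaps at k=2 and k=3 are both 0.5, and the
        tie resolves to the smaller k."""
        S = np.zeros((4, 4))
        S[:2, :2] = [[0.6, 0.2], [0.2, 0.6]]   # normalized eigs {0, 0.5}
        S[2:, 2:] = [[0.5, 0.5], [0.5, 0.5]]   # normalized eigs {0, 1}
        assert fb.estimate_k(S) == 2


class TestCluster:
    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            fb.cluster(np.eye(10), k=1)

    def test_determinism_under_seed(self, chr_data, selection):
        edges, _ = chr_data
        X = edges[:, selection.selected_edges]
        s1, _, _ = fb.simlr(X, k=3, seed=42)
        s2, _, _ = fb.simlr(X, k=3, seed=42)
        np.testing.assert_array_equal(s1.labels, s2.labels)

    def test_planted_biotypes_recovered(self, default_sim, chr_data, selection):
        """ARI vs planted labels on the default synthetic cohort."""
        _, _, _, truth = default_sim
        edges, _ = chr_data
        ari_vals = []
        for seed in range(5):
            sol, _, k_hat = fb.simlr(edges[:, selection.selected_edges], k=3, seed=seed)
            ari_vals.append(adjusted_rand_score(truth.biotype_labels, sol.labels))
        assert np.mean(ari_vals) >= 0.8

    def test_quality_metrics_invariant_to_relabeling(self, default_sim):
        _, _, _, truth = default_sim
        labels = truth.biotype_labels
        permuted = np.choose(labels - 1, [3, 1, 2])
        assert fb.nmi(labels, permuted) == pytest.approx(1.0, abs=1e-12)
        assert adjusted_rand_score(labels, permuted) == pytest.approx(1.0)
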