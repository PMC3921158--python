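import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plinet.connectivity import (ClusterDefinition, DEFAULT_FRONTAL,
                                 DEFAULT_POSTERIOR, ConnectivityMatrix,
                                 cluster_means, connectivity_matrix, dpli,
                                 global_mean_pli, pli)
from plinet.preprocess import PhaseEpoch

N = 4096


def _uniform_matrix(w, n=26):
    m = np.full((n, n), w)
    np.fill_diagonal(m, 0.0)
    labels = tuple(DEFAULT_FRONTAL.labels + DEFAULT_POSTERIOR.labels) + tuple(
        f"x{i}" for i in range(n - 13))
    return ConnectivityMatrix(m, labels)


phase_arrays = st.integers(0, 2 ** 31 - 1).map(
    lambda s: np.random.default_rng(s).uniform(-np.pi, np.pi, size=(2, 64)))


class TestPli:
    def test_constant_nonzero_lag_gives_one(self):
        a = np.full(N, 0.9)
        assert pli(a, a - np.pi / 4) == 1.0

    def test_zero_lag_gives_zero(self):
        a = np.linspace(-np.pi / 2, np.pi / 2, N)
        assert pli(a, a) == 0.0

    def test_cancelling_signs(self):
        assert pli(np.array([0.1, -0.1, 0.2, -0.2]), np.zeros(4)) == 0.0

    def test_hand_computed_third(self):
        assert pli(np.array([0.1, 0.2, -0.3]), np.zeros(3)) == pytest.approx(1 / 3)

    def test_errors(self):
        with pytest.raises(ValueError):
            pli(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            pli(np.array([]), np.array([]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(phase_arrays)
    def test_symmetry(self, ab):
        assert pli(ab[0], ab[1]) == pytest.approx(pli(ab[1], ab[0]), abs=0)


class TestDpli:
    def test_constant_positive_lag_means_leading(self):
        a = np.full(N, 1.0)
        assert dpli(a, a - np.pi / 4) == 1.0

    def test_zero_lag_is_half(self):
        a = np.linspace(0, 1, N)
        assert dpli(a, a) == 0.5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(phase_arrays)
    def test_identity_with_pli_and_antisymmetry(self, ab):
        a, b = ab
        assert abs(2 * dpli(a, b) - 1) == pytest.approx(pli(a, b), abs=1e-15)
        assert dpli(a, b) + dpli(b, a) == pytest.approx(1.0, abs=1e-15)


class TestConnectivityMatrix:
    def test_pairwise_consistency_and_shape(self, rng):
        phases = PhaseEpoch(rng.uniform(-np.pi, np.pi, (6, 256)),
                            tuple("abcdef"))
        mat = connectivity_matrix(phases)
        assert mat.values.shape == (6, 6)
        for i, j in itertools.combinations(range(6), 2):
            assert mat.values[i, j] == pytest.approx(
                pli(phases.phases[i], phases.phases[j]), abs=1e-15)
            assert mat.values[i, j] == mat.values[j, i]
        assert np.all(np.diag(mat.values) == 0)

    def test_26_channels_gives_325_pairs(self, rng):
        labels = tuple(f"c{i}" for i in range(26))
        phases = PhaseEpoch(rng.uniform(-np.pi, np.pi, (26, 128)), labels)
        mat = connectivity_matrix(phases)
        assert np.triu_indices(26, k=1)[0].size == 325
        assert mat.values[np.triu_indices(26, k=1)].size == 325

    def test_single_epoch_mean_is_identity(self, rng):
        phases = PhaseEpoch(rng.uniform(-np.pi, np.pi, (4, 128)), tuple("abcd"))
        one = connectivity_matrix(phases)
        listed = connectivity_matrix([phases])
        assert np.array_equal(one.values, listed.values)

    def test_epoch_average_is_entrywise_mean(self, rng):
        eps = [PhaseEpoch(rng.uniform(-np.pi, np.pi, (4, 64)), tuple("abcd"))
               for _ in range(3)]
        mean_mat = connectivity_matrix(eps).values
        per_epoch = [connectivity_matrix(e).values for e in eps]
        assert np.allclose(mean_mat, np.mean(per_epoch, axis=0))

    def test_inconsistent_labels_rejected(self, rng):
        a = PhaseEpoch(rng.uniform(-1, 1, (2, 16)), ("x", "y"))
        b = PhaseEpoch(rng.uniform(-1, 1, (2, 16)), ("x", "z"))
        with pytest.raises(ValueError, match="inconsistent"):
            connectivity_matrix([a, b])


class TestGlobalMean:
    def test_uniform(self):
        assert global_mean_pli(_uniform_matrix(0.37)) == pytest.approx(0.37)

    def test_three_channel_hand_mean(self):
        m = np.array([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]])
        mat = ConnectivityMatrix(m, ("a", "b", "c"))
        assert global_mean_pli(mat) == pytest.approx(0.4)

    def test_zero_matrix(self):
        mat = ConnectivityMatrix(np.zeros((3, 3)), ("a", "b", "c"))
        assert global_mean_pli(mat) == 0.0

    def test_dpli_matrix_rejected(self):
        mat = ConnectivityMatrix(np.zeros((3, 3)), ("a", "b", "c"),
                                 measure="dpli")
        with pytest.raises(ValueError, match="PLI"):
            global_mean_pli(mat)


class TestClusterMeans:
    def test_uniform_matrix_all_summaries_equal(self):
        cc = cluster_means(_uniform_matrix(0.42))
        assert cc.frontal_short == pytest.approx(0.42)
        assert cc.posterior_short == pytest.approx(0.42)
        assert cc.long_range == pytest.approx(0.42)

    def test_cross_only_construction(self):
        labels = DEFAULT_FRONTAL.labels + DEFAULT_POSTERIOR.labels
        n = len(labels)
        m = np.zeros((n, n))
        m[:7, 7:] = 1.0
        m[7:, :7] = 1.0
        cc = cluster_means(ConnectivityMatrix(m, labels))
        assert cc.long_range == 1.0
        assert cc.frontal_short == 0.0 and cc.posterior_short == 0.0

    def test_default_pair_counts(self):
        f, p = len(DEFAULT_FRONTAL.labels), len(DEFAULT_POSTERIOR.labels)
        assert (f * (f - 1) // 2, p * (p - 1) // 2, f * p) == (21, 15, 42)

    def test_unknown_label_and_overlap_rejected(self):
        mat = _uniform_matrix(0.5)
        with pytest.raises(KeyError):
            cluster_means(mat, ClusterDefinition("frontal", ("Nope",)),
                          DEFAULT_POSTERIOR)
        with pytest.raises(ValueError, match="overlap"):
            cluster_means(mat, DEFAULT_FRONTAL,
                          ClusterDefinition("posterior", ("Fp1", "Pz")))
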