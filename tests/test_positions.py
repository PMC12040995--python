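import itertools

import numpy as np
import pytest

from ectonet.netcore import InteractionMatrix
from ectonet.positions import (
    eigenvector_centrality,
    individual_strength,
    nested_rank,
    position_table,
    project_unipartite,
    specialization_dprime,
)
from tests.conftest import make_bundle, make_matrix, random_matrix


class TestStrength:
    def test_hand_example(self):
        s = individual_strength(make_matrix([[2, 0], [1, 1]]))
        assert s == pytest.approx([2 / 3, 4 / 3])

    def test_identity_conserves(self):
        s = individual_strength(make_matrix([[1, 0], [0, 1]]))
        assert s == pytest.approx([1.0, 1.0])

    def test_conservation_on_random_matrices(self, rng):
        for _ in range(1000):
            m = random_matrix(rng)
            assert individual_strength(m).sum() == pytest.approx(
                m.shape[1], abs=1e-9
            )


class TestNestedRank:
    def test_degree_sorted(self):
        nr = nested_rank(make_matrix([[1, 1, 1], [1, 1, 0], [1, 0, 0]]))
        assert nr == pytest.approx([0.0, 0.5, 1.0])

    def test_two_hosts_endpoints(self):
        nr = nested_rank(make_matrix([[1, 1], [1, 0]]))
        assert nr == pytest.approx([0.0, 1.0])

    def test_abundance_tie_break(self):
        # equal binary degree (2, 2); row totals 5 vs 3 decide the order
        nr = nested_rank(make_matrix([[2, 3], [1, 2]]))
        assert nr == pytest.approx([0.0, 1.0])

    def test_spans_unit_interval(self, rng):
        for _ in range(50):
            nr = nested_rank(random_matrix(rng))
            assert nr.min() == 0.0 and nr.max() == 1.0

    def test_row_shuffle_permutes_ranks(self, rng):
        m = random_matrix(rng, n=8, s=5)
        nr = nested_rank(m)
        perm = rng.permutation(8)
        shuffled = InteractionMatrix(
            m.counts[perm], [m.host_ids[i] for i in perm], m.parasites
        )
        nr_shuffled = nested_rank(shuffled)
        degree = (m.counts > 0).sum(axis=1)
        abund = m.counts.sum(axis=1)
        # hosts with a unique (degree, abundance) key keep their rank
        keys = list(zip(degree, abund))
        for i, k in enumerate(keys):
            if keys.count(k) == 1:
                j = list(perm).index(i)
                assert nr_shuffled[j] == nr[i]

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            nested_rank(random_matrix(rng), method="nodf_search")


def _dprime_oracle(matrix):
    """Integer-allocation normalization of the specialization index.

    For each host, enumerate every allocation of its total A_i over the
    parasite columns subject to the column-total caps and take the maximum
    attainable divergence d_max; the observed d is normalized by that
    integer-constrained maximum (d_min = 0, the same convention as the
    implementation, so the two normalizations differ only in d_max).
    """
    a = matrix.counts.astype(float)
    A_i = a.sum(axis=1).astype(int)
    A_j = a.sum(axis=0).astype(int)
    m = a.sum()
    q = a.sum(axis=0) / m
    out = []
    for i in range(a.shape[0]):
        total = A_i[i]

        def d_of(alloc):
            alloc = np.asarray(alloc, dtype=float)
            p = alloc / total
            mask = alloc > 0
            return (p[mask] * np.log(p[mask] / q[mask])).sum()

        best = max(d_of(alloc) for alloc in _compositions(total, list(A_j)))
        d_obs = d_of(a[i])
        out.append(min(d_obs / best, 1.0) if best > 0 else 0.0)
    return np.asarray(out)


def _compositions(total, caps):
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    for first in range(min(total, caps[0]) + 1):
        for rest in _compositions(total - first, caps[1:]):
            yield (first,) + rest


class TestDprime:
    def test_marginal_proportional_profile_is_zero(self):
        # host rows proportional to the column marginals -> d = 0
        d = specialization_dprime(make_matrix([[2, 4], [1, 2]]))
        assert d == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_diagonal_fully_specialized(self):
        d = specialization_dprime(make_matrix([[5, 0], [0, 5]]))
        assert d == pytest.approx([1.0, 1.0])

    def test_in_unit_interval(self, rng):
        for _ in range(200):
            d = specialization_dprime(random_matrix(rng))
            assert (d >= 0).all() and (d <= 1).all()

    def test_bounded_by_integer_allocation_oracle(self, rng):
        checked = 0
        while checked < 20:
            m = random_matrix(rng, n=3, s=3, max_count=2)
            if m.counts.sum() > 12:
                continue
            checked += 1
            relaxed = specialization_dprime(m)
            oracle = _dprime_oracle(m)
            assert (relaxed <= oracle + 1e-9).all()


class TestProjection:
    def test_sum_method(self):
        w = project_unipartite(make_matrix([[1, 1], [1, 2]]), "sum")
        # shared species p0: 1+1, p1: 1+2 -> w = 5
        assert w[0, 1] == pytest.approx(5.0)
        assert w[0, 0] == 0.0

    def test_no_shared_species_disconnected(self):
        w = project_unipartite(make_matrix([[1, 0], [0, 1]]), "sum")
        assert not w.any()

    def test_binary_counts_shared_species(self):
        w = project_unipartite(make_matrix([[2, 1], [3, 4]]), "binary")
        assert w[0, 1] == 2

    def test_newman_downweights_common_species(self):
        # species p0 on 3 hosts (weight 1/2 each pair), p1 on 2 hosts (weight 1)
        w = project_unipartite(make_matrix([[1, 1], [1, 1], [1, 0]]), "newman")
        assert w[0, 1] == pytest.approx(0.5 + 1.0)
        assert w[0, 2] == pytest.approx(0.5)

    def test_symmetry(self, rng):
        for method in ("sum", "binary", "newman"):
            w = project_unipartite(random_matrix(rng), method)
            assert np.allclose(w, w.T) and np.allclose(np.diag(w), 0)


class TestEigenvectorCentrality:
    def test_complete_graph_equal(self):
        w = np.ones((4, 4)) - np.eye(4)
        assert eigenvector_centrality(w) == pytest.approx([1, 1, 1, 1])

    def test_path_graph(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        assert eigenvector_centrality(w) == pytest.approx(
            [1 / np.sqrt(2), 1.0, 1 / np.sqrt(2)], abs=1e-8
        )

    def test_scale_invariance(self, rng):
        w = rng.random((10, 10))
        w = np.triu(w, 1)
        w = w + w.T
        assert eigenvector_centrality(2 * w) == pytest.approx(
            eigenvector_centrality(w), abs=1e-9
        )

    def test_matches_dense_eigendecomposition(self, rng):
        for _ in range(20):
            w = rng.random((20, 20)) * (rng.random((20, 20)) < 0.4)
            w = np.triu(w, 1)
            w = w + w.T
            if not w.any():
                continue
            vals, vecs = np.linalg.eigh(w)
            lead = np.abs(vecs[:, np.argmax(vals)])
            assert eigenvector_centrality(w) == pytest.approx(
                lead / lead.max(), abs=1e-8
            )

    def test_matches_networkx(self, rng):
        networkx = pytest.importorskip("networkx")
        w = rng.random((12, 12)) * (rng.random((12, 12)) < 0.5)
        w = np.triu(w, 1)
        w = w + w.T
        g = networkx.from_numpy_array(w)
        ref = networkx.eigenvector_centrality_numpy(g, weight="weight")
        ref = np.abs(np.array([ref[i] for i in range(12)]))
        ours = eigenvector_centrality(w)
        assert ours == pytest.approx(ref / ref.max(), abs=1e-6)

    def test_empty_projection_rejected(self):
        with pytest.raises(ValueError, match="no two hosts"):
            eigenvector_centrality(np.zeros((3, 3)))


class TestPositionTable:
    def test_shape_and_ranges(self, small_bundle):
        pt = position_table(small_bundle).table
        assert len(pt) == small_bundle.matrix.shape[0]
        assert pt["strength"].sum() == pytest.approx(small_bundle.matrix.shape[1])
        for col in ("nested_rank", "dprime", "evcent"):
            assert pt[col].between(0, 1).all()
        assert pt["evcent"].max() == pytest.approx(1.0)
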