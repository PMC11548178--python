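"""Geodesic-difference compatibility: first-order, binarized, second-order."""

import numpy as np
import pytest

from geoclique.compat import (
    binarize,
    build_compat_graph,
    first_order_sc,
    geodesic_difference,
    second_order_sc,
    CompatGraph,
)
from geoclique.features import Correspondence, CorrespondenceSet
from geoclique.geodesics import GeodesicMatrix
from geoclique.mesh import InputError


def matrix_from(ids, entries):
    n = len(ids)
    D = np.zeros((n, n))
    for (i, j), v in entries.items():
        a, b = ids.index(i), ids.index(j)
        D[a, b] = D[b, a] = v
    return GeodesicMatrix(np.array(ids), D)


class TestGeodesicDifference:
    def test_identical_pair_is_zero(self):
        D = matrix_from([0, 1], {(0, 1): 1.0})
        c = Correspondence(0, 0, 0.0)
        assert geodesic_difference(c, c, D, D) == 0.0

    def test_absolute_difference(self):
        Ds = matrix_from([0, 1], {(0, 1): 1.0})
        Dt = matrix_from([5, 6], {(5, 6): 1.2})
        ci = Correspondence(0, 5, 0.0)
        cj = Correspondence(1, 6, 0.0)
        assert geodesic_difference(ci, cj, Ds, Dt) == pytest.approx(0.2)
        assert geodesic_difference(cj, ci, Ds, Dt) == pytest.approx(0.2)

    def test_infinite_distance_flags_incompatible(self):
        Ds = matrix_from([0, 1], {(0, 1): np.inf})
        Dt = matrix_from([5, 6], {(5, 6): 1.0})
        out = geodesic_difference(Correspondence(0, 5, 0), Correspondence(1, 6, 0), Ds, Dt)
        assert np.isinf(out)

    def test_missing_vertex_raises(self):
        Ds = matrix_from([0, 1], {(0, 1): 1.0})
        with pytest.raises(KeyError):
            geodesic_difference(
                Correspondence(9, 0, 0), Correspondence(1, 1, 0), Ds, Ds
            )


class TestFirstOrder:
    def test_kernel_values(self):
        S = np.array([[0.0, 0.0], [0.0, 0.0]])
        assert first_order_sc(S, d=0.05)[0, 1] == 1.0
        S = np.array([[0.0, 0.05], [0.05, 0.0]])
        assert first_order_sc(S, d=0.05)[0, 1] == pytest.approx(np.exp(-1), abs=1e-9)

    def test_monotonically_decreasing(self):
        s = np.linspace(0, 0.3, 50)
        S = np.zeros((2, 2))
        vals = []
        for x in s:
            S[0, 1] = S[1, 0] = x
            vals.append(first_order_sc(S, d=0.05)[0, 1])
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_nonpositive_d_rejected(self):
        with pytest.raises(InputError):
            first_order_sc(np.zeros((2, 2)), d=0.0)


class TestBinarize:
    def test_strict_threshold(self):
        SC1 = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert binarize(SC1, 0.99)[0, 1] == 1
        SC1 = np.array([[0.0, 0.99], [0.99, 0.0]])
        assert binarize(SC1, 0.99)[0, 1] == 0  # equality maps to 0

    def test_tau_bounds(self):
        for tau in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(InputError):
                binarize(np.zeros((2, 2)), tau)


class TestSecondOrder:
    def test_triangle_and_complete_graph(self):
        tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        SC2 = second_order_sc(tri)
        assert SC2[0, 1] == 1  # single common neighbor (vertex 2)
        K4 = 1 - np.eye(4, dtype=int)
        SC2 = second_order_sc(K4)
        off = ~np.eye(4, dtype=bool)
        assert (SC2[off] == 2).all()

    def test_masking_by_missing_edge(self):
        # 0-2, 1-2 edges but no 0-1 edge: common neighbor exists, entry still 0
        C = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]])
        assert second_order_sc(C)[0, 1] == 0

    @pytest.mark.parametrize("n,seed", [(10, 0), (25, 1), (50, 2), (50, 3)])
    def test_equals_bruteforce_triple_loop(self, n, seed):
        rng = np.random.default_rng(seed)
        C = np.triu((rng.random((n, n)) < 0.4).astype(int), 1)
        C = C + C.T
        SC2 = second_order_sc(C)
        ref = np.zeros_like(C)
        for i in range(n):
            for j in range(n):
                if C[i, j]:
                    ref[i, j] = sum(C[i, k] * C[k, j] for k in range(n))
        assert np.array_equal(SC2, ref)

    def test_non_binary_rejected(self):
        with pytest.raises(InputError):
            second_order_sc(np.full((3, 3), 0.5))


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(min_value=2, max_value=20), st.integers(min_value=0, max_value=10**6))
def test_second_order_structural_properties(n, seed):
    """Symmetry, masking, and the n-2 ceiling hold on arbitrary graphs."""
    rng = np.random.default_rng(seed)
    C = np.triu((rng.random((n, n)) < rng.uniform(0, 1)).astype(int), 1)
    C = C + C.T
    SC2 = second_order_sc(C)
    assert np.array_equal(SC2, SC2.T)
    assert (SC2[C == 0] == 0).all()
    off = ~np.eye(n, dtype=bool)
    assert SC2[off].max(initial=0) <= n - 2
    assert (np.diag(SC2) == 0).all()


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    st.floats(min_value=1e-6, max_value=10.0),
    st.floats(min_value=0.0, max_value=100.0),
    st.floats(min_value=0.0, max_value=100.0),
)
def test_geman_mcclure_properties(sigma, s1, s2):
    """Bounded in [0, 1) and monotone in |s| for any positive scale."""
    from geoclique.fitting import geman_mcclure

    lo, hi = sorted([s1, s2])
    assert 0.0 <= geman_mcclure(lo, sigma) <= geman_mcclure(hi, sigma) < 1.0


def planted_graph(n_inliers, n_outliers, seed=0, drift=1.0):
    """Compatibility graph from synthetic distance matrices: inliers have
    identical source/target geodesics, outliers drift by ``drift`` meters."""
    rng = np.random.default_rng(seed)
    n = n_inliers + n_outliers
    ids_s = list(range(n))
    ids_t = list(range(100, 100 + n))
    base = rng.uniform(0.3, 1.5, size=(n, n))
    base = np.triu(base, 1)
    base = base + base.T
    Ds = GeodesicMatrix(np.array(ids_s), base)
    Dt_mat = base.copy()
    for o in range(n_inliers, n):
        noise = rng.uniform(0.5, 1.0, size=n) * drift
        Dt_mat[o, :] = base[o, :] + noise
        Dt_mat[:, o] = Dt_mat[o, :]
        Dt_mat[o, o] = 0.0
    Dt = GeodesicMatrix(np.array(ids_t), Dt_mat)
    corrs = CorrespondenceSet(
        [Correspondence(i, 100 + i, 0.0) for i in range(n)]
    )
    return corrs, Ds, Dt


class TestBuildCompatGraph:
    def test_planted_inliers_complete(self):
        corrs, Ds, Dt = planted_graph(10, 0)
        g = build_compat_graph(corrs, Ds, Dt)
        off = ~np.eye(10, dtype=bool)
        assert (g.C_bin[off] == 1).all()
        assert (g.SC2[off] == 8).all()  # n - 2 on a complete graph

    def test_single_correspondence(self):
        corrs, Ds, Dt = planted_graph(1, 0)
        g = build_compat_graph(corrs, Ds, Dt)
        assert g.n == 1
        for M in (g.S_geo, g.SC1, g.C_bin, g.SC2):
            assert M.shape == (1, 1) and M[0, 0] == 0

    def test_outlier_rows_zero(self):
        corrs, Ds, Dt = planted_graph(8, 3, seed=1)
        g = build_compat_graph(corrs, Ds, Dt)
        assert (g.SC2[8:, :] == 0).all()
        assert (g.C_bin[8:, :] == 0).all()

    def test_inlier_separation_bound(self):
        # inlier-inlier second-order compatibility is at least m - 2
        for m, k, seed in [(10, 5, 0), (20, 20, 1), (15, 40, 2)]:
            corrs, Ds, Dt = planted_graph(m, k, seed=seed)
            g = build_compat_graph(corrs, Ds, Dt)
            inl = np.arange(m)
            block = g.SC2[np.ix_(inl, inl)]
            off = ~np.eye(m, dtype=bool)
            assert block[off].min() >= m - 2

    def test_npz_and_edge_tsv_round_trip(self, tmp_path):
        corrs, Ds, Dt = planted_graph(6, 2, seed=3)
        g = build_compat_graph(corrs, Ds, Dt)
        p = tmp_path / "g.npz"
        g.save(p)
        back = CompatGraph.load(p)
        assert np.array_equal(back.SC2, g.SC2)
        assert back.tau_cmp == g.tau_cmp
        tsv = tmp_path / "g.tsv"
        g.save_edge_tsv(tsv)
        lines = tsv.read_text().strip().splitlines()
        assert len(lines) - 1 == int(np.triu(g.C_bin, 1).sum())
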