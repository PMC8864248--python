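import numpy as np
import pytest

from scsge import (
    BoxSpec,
    CellNetwork,
    ValidationError,
    box_membership,
    build_all_networks,
    build_cell_network,
    degree_report,
    dependency_index,
)
from scsge.matrix import TimeCourse
from scsge.network import _loglog_fit
from conftest import make_matrix
import reference


class TestBoxMembership:
    def test_window_around_value_with_tie_rule(self):
        values = np.arange(1.0, 11.0)  # cell i has value i+1
        box = box_membership(values, k=4, spec=BoxSpec(0.2))  # value 5, b=2
        # values 4 and 6 are equidistant; smaller index (value 4) wins
        assert set(box) == {3, 4}

    def test_fraction_one_is_whole_sample(self, rng):
        values = rng.normal(size=10)
        assert set(box_membership(values, 3, BoxSpec(1.0))) == set(range(10))

    def test_all_identical_values_take_smallest_indices(self):
        values = np.zeros(10)
        assert set(box_membership(values, 9, BoxSpec(0.3))) == {0, 1, 2}

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            values = np.round(rng.normal(size=13), 1)  # rounding forces ties
            k = int(rng.integers(13))
            b = BoxSpec(0.23).box_size(13)
            assert set(box_membership(values, k, BoxSpec(0.23))) == reference.ref_box(
                list(values), k, b
            )


class TestDependencyIndex:
    def test_maximal_overlap(self):
        box = set(range(10))
        assert dependency_index(box, box, 100) == pytest.approx(0.09)

    def test_independence_point(self):
        assert dependency_index(set(range(10)), {9, *range(50, 59)}, 100) == pytest.approx(0.0)

    def test_identical_rankings_toy(self):
        # two genes with identical value rankings over 10 cells, b=2
        g1 = np.arange(10.0)
        g2 = np.arange(10.0) * 7 + 1
        b = BoxSpec(0.2).box_size(10)
        for k in range(10):
            bi = set(box_membership(g1, k, BoxSpec(0.2)))
            bj = set(box_membership(g2, k, BoxSpec(0.2)))
            assert dependency_index(bi, bj, 10) == pytest.approx(0.16)
            assert b == 2


class TestBuildCellNetwork:
    def test_identical_ranking_pair_edge_weight(self):
        m = make_matrix(np.vstack([np.arange(10.0), np.arange(10.0) * 2]))
        net = build_cell_network(m, 4, BoxSpec(0.2))
        assert list(net.edges()) == [("g0", "g1", pytest.approx(0.2 - 0.04))]

    def test_disjoint_boxes_give_no_edge(self):
        # gene 1 all zeros: its box is the 2 smallest-index cells; centering
        # on the last cell of an increasing gene 0 makes the boxes disjoint
        m = make_matrix(np.vstack([np.arange(10.0), np.zeros(10)]))
        net = build_cell_network(m, 9, BoxSpec(0.2))
        assert net.n_edges == 0
        r = reference.ref_r(list(m.values[0]), list(m.values[1]), 9, 2)
        assert r == pytest.approx(-0.04)

    def test_requires_normalized_input(self, rng):
        m = make_matrix(rng.lognormal(size=(3, 10)), normalized=False)
        with pytest.raises(ValidationError, match="normalized"):
            build_cell_network(m, 0)

    def test_matches_bruteforce_all_cells(self, random_matrix):
        spec = BoxSpec(0.25)
        for k in range(random_matrix.n_cells):
            net = build_cell_network(random_matrix, k, spec)
            got = {
                (random_matrix.gene_ids.index(a), random_matrix.gene_ids.index(b)): w
                for a, b, w in net.edges()
            }
            assert got == pytest.approx(reference.ref_network(random_matrix.values, k, 0.25))

    def test_permutation_equivariance(self, rng, continuous_matrix):
        perm = rng.permutation(continuous_matrix.n_cells)
        shuffled = make_matrix(
            continuous_matrix.values[:, perm],
            cells=[continuous_matrix.cell_ids[p] for p in perm],
        )
        for k_new, k_old in enumerate(perm):
            a = {(x, y): w for x, y, w in build_cell_network(shuffled, k_new).edges()}
            b = {(x, y): w for x, y, w in build_cell_network(continuous_matrix, int(k_old)).edges()}
            assert set(a) == set(b)
            for key in a:
                assert a[key] == pytest.approx(b[key])

    def test_cell_duplication_invariance(self, continuous_matrix):
        doubled = make_matrix(
            np.concatenate([continuous_matrix.values, continuous_matrix.values], axis=1),
            cells=continuous_matrix.cell_ids + [c + "_dup" for c in continuous_matrix.cell_ids],
        )
        spec = BoxSpec(0.25)
        for k in range(continuous_matrix.n_cells):
            orig = {(x, y): w for x, y, w in build_cell_network(continuous_matrix, k, spec).edges()}
            dup = {(x, y): w for x, y, w in build_cell_network(doubled, k, spec).edges()}
            assert set(orig) == set(dup)
            for key in orig:
                assert dup[key] == pytest.approx(orig[key])

    def test_positive_scaling_of_one_gene_is_invariant(self, random_matrix):
        scaled = make_matrix(
            np.vstack([random_matrix.values[0] * 3.7, random_matrix.values[1:]]),
            cells=random_matrix.cell_ids,
        )
        for k in range(random_matrix.n_cells):
            a = build_cell_network(random_matrix, k)
            b = build_cell_network(scaled, k)
            assert (a.adjacency != b.adjacency).nnz == 0

    def test_weight_bound(self, random_matrix):
        f = 0.25
        for k in range(random_matrix.n_cells):
            net = build_cell_network(random_matrix, k, BoxSpec(f))
            if net.adjacency.nnz:
                assert net.adjacency.data.max() <= f - f**2 + 1e-12


class TestBuildAllNetworks:
    def test_one_network_per_cell(self, rng):
        mats = [make_matrix(np.log1p(rng.lognormal(size=(4, 20)))) for _ in range(2)]
        tc = TimeCourse(mats, [0.0, 12.0])
        nets = build_all_networks(tc)
        assert [len(g) for g in nets] == [20, 20]
        assert nets[0][3].cell_id == mats[0].cell_ids[3]


class TestDegreeReport:
    def test_path_and_star_statistics(self):
        genes = [f"g{i}" for i in range(5)]
        path = CellNetwork.from_edges("path", genes[:3], [("g0", "g1", 0.1), ("g1", "g2", 0.1)])
        star = CellNetwork.from_edges(
            "star", genes, [("g0", g, 0.2) for g in genes[1:]]
        )
        rep = degree_report([path, star])
        assert rep.per_cell_mean_degree["path"] == pytest.approx(4 / 3)
        # star histogram {1: 4, 4: 1} plus path degrees {1: 2, 2: 1}
        assert rep.degree_histogram == {1: 6, 2: 1, 4: 1}

    def test_exact_power_law_fit(self):
        hist = {d: int(1024 * d**-2) for d in (1, 2, 4, 8, 16)}
        slope, r2 = _loglog_fit(hist)
        assert slope == pytest.approx(-2.0, abs=0.01)
        assert r2 >= 0.999

    def test_empty_networks_report_zeros(self):
        genes = ["g0", "g1"]
        empty = CellNetwork.from_edges("empty", genes, [])
        rep = degree_report([empty])
        assert rep.per_cell_mean_degree["empty"] == 0.0
        assert rep.degree_histogram == {}
        assert rep.powerlaw_slope == 0.0 and rep.powerlaw_r2 == 0.0
        assert rep.per_cell_scale_free["empty"] is False
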