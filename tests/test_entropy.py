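import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scsge import (
    BoxSpec,
    CellNetwork,
    ValidationError,
    build_cell_network,
    build_entropy_series,
    cell_sge,
    entropy_from_expression,
    local_entropy_matrix,
    local_network,
    local_sge,
    timepoint_sge,
    timepoint_summary,
)
from conftest import make_matrix
import reference


def star_network(cell_id="c0", n_leaves=4, weight=0.05):
    genes = [f"g{i}" for i in range(n_leaves + 1)]
    return CellNetwork.from_edges(
        cell_id, genes, [("g0", g, weight) for g in genes[1:]]
    )


class TestLocalNetwork:
    def test_star_center_and_leaf(self):
        net = star_network()
        ids, w = local_network(net, "g0")
        assert len(ids) == 4 and np.all(w == 0.05)
        ids, w = local_network(net, "g3")
        assert ids == ["g0"] and w[0] == 0.05

    def test_isolated_gene_and_unknown_gene(self):
        net = CellNetwork.from_edges("c0", ["g0", "g1", "g2"], [("g0", "g1", 0.1)])
        assert local_network(net, "g2")[0] == []
        with pytest.raises(ValidationError, match="unknown"):
            local_network(net, "nope")


class TestLocalSge:
    def test_uniform_masses_give_maximal_entropy(self):
        assert local_sge([0.2] * 4, [1.0] * 4) == pytest.approx(1.0)

    def test_degenerate_mass_gives_zero(self):
        assert local_sge([0.1, 0.1, 0.1], [1.0, 0.0, 0.0]) == 0.0

    def test_direct_evaluation(self):
        # masses (1, 1, 2) over 3 neighbors
        assert local_sge([1.0, 1.0, 2.0], [1.0, 1.0, 1.0]) == pytest.approx(
            0.9464, abs=1e-4
        )

    @pytest.mark.parametrize("weights,exprs", [([], []), ([0.5], [1.0])])
    def test_small_neighborhoods_return_zero(self, weights, exprs):
        assert local_sge(weights, exprs) == 0.0

    def test_all_zero_expression_returns_zero(self):
        assert local_sge([0.1, 0.2], [0.0, 0.0]) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            local_sge([0.1, -0.1], [1.0, 1.0])
        with pytest.raises(ValidationError):
            local_sge([0.1, 0.1], [1.0, -1.0])

    def test_weight_modes_coincide_when_expression_is_flat(self, rng):
        w = rng.uniform(0.01, 0.09, size=6)
        e_flat = np.full(6, 2.5)
        assert local_sge(w, e_flat, "product") == pytest.approx(
            local_sge(w, e_flat, "r_only"), abs=1e-12
        )
        e_varied = rng.lognormal(size=6)
        assert local_sge(w, e_varied, "product") != pytest.approx(
            local_sge(w, e_varied, "r_only"), abs=1e-6
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_entropy_law(self, data):
        """H in [0,1]; 1 iff uniform masses (S>=2); 0 iff degenerate."""
        s = data.draw(st.integers(min_value=2, max_value=30))
        w = data.draw(
            st.lists(st.floats(0.01, 1.0), min_size=s, max_size=s)
        )
        e = data.draw(
            st.lists(st.floats(0.0, 5.0), min_size=s, max_size=s)
        )
        h = local_sge(w, e, "product")
        assert 0.0 <= h <= 1.0
        masses = np.array(w) * np.array(e)
        if masses.sum() > 0:
            p = masses / masses.sum()
            if np.ptp(p) < 1e-12:
                assert h == pytest.approx(1.0, abs=1e-9)
            elif np.ptp(p) > 1e-6:
                assert h < 1.0
            if np.count_nonzero(p) == 1:
                assert h == 0.0
            elif np.count_nonzero(p) >= 2:
                assert h > 0.0


class TestLocalEntropyMatrix:
    def test_all_empty_networks_give_zero_matrix(self, rng):
        m = make_matrix(np.log1p(rng.lognormal(size=(3, 10))))
        nets = [
            CellNetwork.from_edges(c, m.gene_ids, []) for c in m.cell_ids
        ]
        lem = local_entropy_matrix(nets, m)
        assert np.all(lem.values == 0.0)

    def test_star_with_flat_expression(self):
        vals = np.full((5, 10), 2.0)
        m = make_matrix(vals)
        nets = [star_network(c) for c in m.cell_ids]
        lem = local_entropy_matrix(nets, m)
        np.testing.assert_allclose(lem.values[0, :], 1.0)
        np.testing.assert_array_equal(lem.values[1:, :], 0.0)

    def test_matches_bruteforce(self, rng):
        vals = np.log1p(rng.lognormal(size=(6, 12)))
        vals[rng.random((6, 12)) < 0.2] = 0.0
        m = make_matrix(vals)
        spec = BoxSpec(0.2)
        nets = [build_cell_network(m, k, spec) for k in range(12)]
        for mode in ("product", "r_only", "expr_only"):
            lem = local_entropy_matrix(nets, m, mode)
            ref = reference.ref_local_entropy_matrix(vals, 0.2, mode)
            np.testing.assert_allclose(lem.values, ref, atol=1e-12)

    def test_fused_path_equals_contract_path(self, random_matrix):
        spec = BoxSpec(0.25)
        nets = [
            build_cell_network(random_matrix, k, spec)
            for k in range(random_matrix.n_cells)
        ]
        contract = local_entropy_matrix(nets, random_matrix)
        fused = entropy_from_expression(random_matrix, spec)
        np.testing.assert_allclose(fused.values, contract.values, atol=1e-12)


class TestCellAndTimepointSge:
    def test_top_fraction_selection(self):
        col = np.array([0.9, 0.5, 0.1, 0.8])
        assert cell_sge(col, 0.05) == (pytest.approx(0.9), 1)
        assert cell_sge(col, 0.5) == (pytest.approx(1.7), 2)

    def test_all_equal_column(self):
        h, t = cell_sge(np.full(20, 0.3), 0.25)
        assert t == 5 and h == pytest.approx(1.5)

    def test_matches_bruteforce(self, rng):
        col = rng.random(37)
        for f in (0.01, 0.05, 0.33, 1.0):
            assert cell_sge(col, f) == pytest.approx(reference.ref_cell_sge(list(col), f))

    def test_timepoint_mean_and_summary(self):
        assert timepoint_sge([1.0, 2.0, 3.0]) == 2.0
        assert timepoint_sge([7.5]) == 7.5
        s = timepoint_summary([1.0, 2.0, 3.0, 4.0])
        assert s["median"] == 2.5 and s["n"] == 4
        with pytest.raises(ValidationError):
            timepoint_sge([])

    def test_sampling_mean_within_three_standard_errors(self, rng):
        draws = rng.normal(5.0, 2.0, size=1000)
        assert abs(timepoint_sge(draws) - 5.0) <= 3 * 2.0 / math.sqrt(1000)

    def test_series_aggregation(self, rng):
        from scsge.entropy import LocalEntropyMatrix

        lems = [
            LocalEntropyMatrix(
                rng.random((8, 10)), [f"g{i}" for i in range(8)],
                [f"t{t}c{k}" for k in range(10)],
            )
            for t in range(3)
        ]
        series = build_entropy_series(lems, [0.0, 1.0, 2.0], 0.25)
        assert series.t_used == 2
        for tp, lem in zip(series.per_timepoint, lems):
            expect = np.sort(lem.values, axis=0)[-2:, :].sum(axis=0)
            np.testing.assert_allclose(tp.per_cell, expect)
            assert tp.h_t == pytest.approx(expect.mean())
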