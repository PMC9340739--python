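"""Input-output algebra: coefficients, inverses, perspectives, net flows."""

import numpy as np
import pytest

from pahflow.inventory import split_anthropogenic
from pahflow.mrio import (
    MRIOTable,
    NonProductiveEconomyError,
    PerspectiveEmissions,
    aggregate_regions,
    consumption_based,
    deflate,
    emission_intensity,
    four_perspectives,
    ghosh_inverse,
    input_coefficients,
    leontief_inverse,
    net_flows,
    output_coefficients,
)

from conftest import build_balanced_table


def tiny_table():
    """Two sectors, one region: Z=[[2,1],[0,3]], x=[10,5]."""
    Z = np.array([[2.0, 1.0], [0.0, 3.0]])
    x = np.array([10.0, 5.0])
    Fd = (x - Z.sum(axis=1))[:, None]
    v = x - Z.sum(axis=0)
    return MRIOTable(Z=Z, Fd=Fd, v=v, x=x, n_regions=1, n_sectors=2)


class TestCoefficients:
    def test_input_coefficients_divide_columns_by_output(self):
        A = input_coefficients(tiny_table())
        np.testing.assert_allclose(A, [[0.2, 0.2], [0.0, 0.6]])

    def test_output_coefficients_divide_rows_by_output(self):
        B = output_coefficients(tiny_table())
        np.testing.assert_allclose(B, [[0.2, 0.1], [0.0, 0.6]])

    def test_zero_flows_give_zero_coefficients(self):
        t = tiny_table()
        t.Z = np.zeros((2, 2))
        assert not input_coefficients(t).any()
        assert not output_coefficients(t).any()

    def test_zero_output_sector_is_convention_not_error(self):
        t = tiny_table()
        t.Z = np.array([[2.0, 0.0], [0.0, 0.0]])
        t.x = np.array([10.0, 0.0])
        A = input_coefficients(t)
        B = output_coefficients(t)
        assert not A[:, 1].any()
        assert not B[1, :].any()


class TestInverses:
    def test_zero_coefficients_give_identity(self):
        np.testing.assert_array_equal(leontief_inverse(np.zeros((3, 3))), np.eye(3))

    def test_leontief_matches_neumann_series(self):
        A = np.array([[0.2, 0.3], [0.1, 0.4]])
        L = leontief_inverse(A)
        series = sum(np.linalg.matrix_power(A, k) for k in range(61))
        assert np.abs(L - series).max() < 1e-10

    def test_defining_identities(self):
        rng = np.random.default_rng(3)
        t = build_balanced_table(rng, 2, 3)
        A, B = input_coefficients(t), output_coefficients(t)
        L, G = leontief_inverse(A), ghosh_inverse(B)
        n = t.n
        assert np.abs(L @ (np.eye(n) - A) - np.eye(n)).max() < 1e-8
        assert np.abs(G - (np.eye(n) + B @ G)).max() < 1e-8
        # total requirements always dominate the direct ones
        assert np.all(L - np.eye(n) > -1e-12)
        assert np.all(G - np.eye(n) > -1e-12)

    def test_non_productive_economy_rejected(self):
        with pytest.raises(NonProductiveEconomyError):
            leontief_inverse(np.array([[1.0]]))


class TestPerspectives:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_four_conserve_total_emissions(self, seed):
        rng = np.random.default_rng(seed)
        t = build_balanced_table(rng, 3, 2)
        E = rng.uniform(0.0, 5.0, size=(3, 2))
        qs = four_perspectives(t, E)
        for q in qs.values():
            assert q.total == pytest.approx(E.sum(), rel=1e-8)

    def test_row_sums_reproduce_production_emissions(self):
        rng = np.random.default_rng(11)
        t = build_balanced_table(rng, 3, 2)
        E = rng.uniform(0.0, 5.0, size=(3, 2))
        qs = four_perspectives(t, E)
        per_region = E.sum(axis=1)
        for q in qs.values():
            np.testing.assert_allclose(q.emitted_by_region(), per_region, rtol=1e-8)

    def test_single_region_world_collapses_to_total(self):
        rng = np.random.default_rng(5)
        t = build_balanced_table(rng, 1, 3)
        E = rng.uniform(0.0, 5.0, size=(1, 3))
        for q in four_perspectives(t, E).values():
            assert q.Qmat.shape == (1, 1)
            assert q.Qmat[0, 0] == pytest.approx(E.sum(), rel=1e-10)

    def test_zero_intensity_gives_zero_everywhere(self):
        rng = np.random.default_rng(6)
        t = build_balanced_table(rng, 2, 2)
        for q in four_perspectives(t, np.zeros((2, 2))).values():
            assert not q.Qmat.any()

    def test_zero_final_demand_region_has_zero_consumption_column(self):
        rng = np.random.default_rng(8)
        t = build_balanced_table(rng, 3, 2, zero_demand_regions=(1,))
        u = emission_intensity(rng.uniform(0, 2, size=t.n), t.x)
        L = leontief_inverse(input_coefficients(t))
        q = consumption_based(u, L, t.Fd, 3, 2)
        assert not q.Qmat[:, 1].any()


class TestAggregation:
    def _q(self):
        rng = np.random.default_rng(9)
        return PerspectiveEmissions("consumption", rng.uniform(0, 3, (4, 4)),
                                    [f"R{i}" for i in range(4)])

    def test_identity_mapping_is_noop(self):
        q = self._q()
        out = aggregate_regions(q, {m: m for m in range(4)})
        np.testing.assert_array_equal(out.Qmat, q.Qmat)

    def test_all_to_one_gives_grand_total(self):
        q = self._q()
        out = aggregate_regions(q, {m: 0 for m in range(4)})
        assert out.Qmat.shape == (1, 1)
        assert out.Qmat[0, 0] == pytest.approx(q.total)

    def test_two_block_mapping_matches_explicit_sums(self):
        q = self._q()
        out = aggregate_regions(q, {0: 0, 1: 0, 2: 1, 3: 1})
        expected = np.array([
            [q.Qmat[:2, :2].sum(), q.Qmat[:2, 2:].sum()],
            [q.Qmat[2:, :2].sum(), q.Qmat[2:, 2:].sum()],
        ])
        np.testing.assert_allclose(out.Qmat, expected)

    def test_partial_mapping_rejected(self):
        with pytest.raises(ValueError, match="mapping"):
            aggregate_regions(self._q(), {0: 0, 1: 0})


class TestNetFlows:
    def test_symmetric_matrix_has_no_net_flow(self):
        q = PerspectiveEmissions("sale", np.array([[1.0, 2.0], [2.0, 3.0]]), ["a", "b"])
        nf = net_flows(q)
        assert not nf.netflow.any()
        assert nf.importers == [] and nf.exporters == []

    def test_directional_example(self):
        q = PerspectiveEmissions("consumption", np.array([[0.0, 3.0], [1.0, 0.0]]), ["a", "b"])
        nf = net_flows(q)
        # 3 units emitted in region 0 for region 1's driver, 1 the reverse
        assert nf.netflow[0, 1] == 2.0
        assert nf.importers == [1] and nf.exporters == [0]
        assert nf.total_net_inflow == 2.0

    def test_antisymmetry_by_construction(self):
        rng = np.random.default_rng(10)
        q = PerspectiveEmissions("income", rng.uniform(0, 5, (5, 5)), list("abcde"))
        nf = net_flows(q)
        np.testing.assert_array_equal(nf.netflow, -nf.netflow.T)

    def test_requires_square_matrix(self):
        q = PerspectiveEmissions("consumption", np.ones((3, 2)), ["a", "b", "c"])
        with pytest.raises(ValueError):
            net_flows(q)


class TestDeflate:
    def test_unit_deflators_leave_table_unchanged(self):
        rng = np.random.default_rng(12)
        t = build_balanced_table(rng, 2, 2)
        out = deflate(t, np.ones(2))
        np.testing.assert_allclose(out.Z, t.Z)
        np.testing.assert_allclose(out.x, t.x)

    def test_uniform_deflator_scales_but_preserves_coefficients(self):
        rng = np.random.default_rng(13)
        t = build_balanced_table(rng, 2, 2)
        out = deflate(t, np.full(2, 2.0))
        np.testing.assert_allclose(out.Z, t.Z / 2.0)
        np.testing.assert_allclose(input_coefficients(out), input_coefficients(t), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_heterogeneous_deflators_rebalance(self, seed):
        rng = np.random.default_rng(seed)
        t = build_balanced_table(rng, 3, 2)
        d = rng.uniform(0.9, 1.1, size=3)
        deflate(t, d).validate(rtol=1e-8)

    def test_nonpositive_deflator_rejected(self):
        rng = np.random.default_rng(14)
        t = build_balanced_table(rng, 2, 2)
        with pytest.raises(ValueError):
            deflate(t, np.array([1.0, 0.0]))


def test_generated_world_perspectives_conserve(default_world):
    anthro, _ = split_anthropogenic(default_world[0].inventory)
    qs = four_perspectives(default_world[0].table, anthro.E)
    for q in qs.values():
        assert q.total == pytest.approx(anthro.E.sum(), rel=1e-8)
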