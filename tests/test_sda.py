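"""Structural decomposition: completeness, oracles, driver recovery."""

import numpy as np
import pytest

from pahflow import generate_world, single_driver_world
from pahflow.inventory import split_anthropogenic
from pahflow.mrio import four_perspectives
from pahflow.sda import (
    DECOMPOSABLE_PERSPECTIVES,
    FactorSet,
    build_factors,
    full_average_sda,
    health_driver_decomposition,
    two_polar_sda,
)


def scalar_factorset(values, names=None, year=0):
    values = [np.atleast_2d(np.asarray(v, dtype=float)) for v in values]
    names = tuple(names or [f"f{i}" for i in range(len(values))])
    return FactorSet(perspective="consumption", names=names, factors=values,
                     n_regions=1, n_sectors=1, orientation="emit_rows", year=year)


def random_factorset(rng, year=0, n_regions=2, n_sectors=3):
    """Random six-factor chain with the consumption-perspective shapes."""
    N = n_regions * n_sectors
    factors = [
        np.diag(rng.uniform(0.1, 2.0, N)),
        np.diag(rng.uniform(0.1, 2.0, N)),
        np.eye(N) + rng.uniform(0, 0.5, (N, N)),
        rng.uniform(0.1, 1.0, (N, n_regions)),
        np.diag(rng.uniform(0.5, 2.0, n_regions)),
        np.diag(rng.uniform(1.0, 5.0, n_regions)),
    ]
    names = ("emission_factors", "energy_efficiency", "production_structure",
             "demand_structure", "demand_level", "population")
    return FactorSet(perspective="consumption", names=names, factors=factors,
                     n_regions=n_regions, n_sectors=n_sectors,
                     orientation="emit_rows", year=year)


class TestTwoPolar:
    def test_identical_endpoints_give_zero_contributions(self):
        rng = np.random.default_rng(0)
        f = random_factorset(rng)
        r = two_polar_sda(f, f)
        assert all(v == 0.0 for v in r.contributions.values())
        assert r.delta_total == 0.0

    def test_scalar_two_factor_hand_example(self):
        # Q = k*p with k: 1->2, p: 3->4; polar forms average to 3.5 and 1.5
        f0 = scalar_factorset([1.0, 3.0], names=("k", "p"), year=0)
        f1 = scalar_factorset([2.0, 4.0], names=("k", "p"), year=1)
        r = two_polar_sda(f0, f1)
        assert r.contributions["k"] == pytest.approx(3.5)
        assert r.contributions["p"] == pytest.approx(1.5)
        assert r.delta_total == pytest.approx(5.0)
        assert r.residual == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_six_factor_completeness(self, seed):
        rng = np.random.default_rng(seed)
        f0, f1 = random_factorset(rng, year=0), random_factorset(rng, year=1)
        r = two_polar_sda(f0, f1)
        assert abs(r.residual) < 1e-10 * max(1.0, abs(r.delta_total))

    def test_antisymmetry_under_time_reversal(self):
        rng = np.random.default_rng(42)
        f0, f1 = random_factorset(rng, 0), random_factorset(rng, 1)
        fwd = two_polar_sda(f0, f1)
        bwd = two_polar_sda(f1, f0)
        for name in fwd.contributions:
            assert bwd.contributions[name] == pytest.approx(-fwd.contributions[name], rel=1e-10)

    def test_shape_mismatch_rejected(self):
        f0 = scalar_factorset([1.0, 2.0])
        f1 = random_factorset(np.random.default_rng(0))
        with pytest.raises(ValueError):
            two_polar_sda(f0, f1)


class TestFullAverageOracle:
    def test_two_factor_case_coincides_with_two_polar(self):
        f0 = scalar_factorset([1.5, 2.0], names=("a", "b"), year=0)
        f1 = scalar_factorset([2.5, 5.0], names=("a", "b"), year=1)
        tp, fa = two_polar_sda(f0, f1), full_average_sda(f0, f1)
        for name in tp.contributions:
            assert fa.contributions[name] == pytest.approx(tp.contributions[name], rel=1e-12)

    def test_three_factor_scalars_both_complete(self):
        rng = np.random.default_rng(1)
        f0 = scalar_factorset(rng.uniform(0.5, 2, 3), year=0)
        f1 = scalar_factorset(rng.uniform(0.5, 2, 3), year=1)
        tp, fa = two_polar_sda(f0, f1), full_average_sda(f0, f1)
        assert abs(tp.residual) < 1e-12
        assert abs(fa.residual) < 1e-12
        # methods may differ per factor, but only within the total change
        spread = max(abs(tp.contributions[n] - fa.contributions[n]) for n in tp.contributions)
        assert spread <= abs(tp.delta_total)

    def test_six_factor_matrix_instance_complete(self):
        rng = np.random.default_rng(2)
        f0, f1 = random_factorset(rng, 0), random_factorset(rng, 1)
        fa = full_average_sda(f0, f1)
        assert abs(fa.residual) < 1e-10 * max(1.0, abs(fa.delta_total))

    def test_enumeration_limit_enforced(self):
        f0 = scalar_factorset(np.ones(8))
        f1 = scalar_factorset(np.ones(8))
        with pytest.raises(ValueError, match="enumeration"):
            full_average_sda(f0, f1)


class TestBuildFactors:
    @pytest.mark.parametrize("perspective", DECOMPOSABLE_PERSPECTIVES)
    def test_product_reconstructs_direct_footprint(self, default_world, perspective):
        sl = default_world[0]
        anthro, _ = split_anthropogenic(sl.inventory)
        direct = four_perspectives(sl.table, anthro.E)[perspective]
        f = build_factors(sl, perspective=perspective)
        assert f.total == pytest.approx(direct.total, rel=1e-6)
        np.testing.assert_allclose(f.emissions_by_region(), direct.emitted_by_region(),
                                   rtol=1e-6)

    def test_intensity_reconstruction(self, default_world):
        # emission-factor times energy-efficiency diagonals equal E/x
        sl = default_world[0]
        f = build_factors(sl, perspective="consumption")
        K, Teff = np.diag(f.factors[0]), np.diag(f.factors[1])
        u = sl.inventory.E.ravel() / sl.table.x
        np.testing.assert_allclose(K * Teff, u, rtol=1e-8)

    def test_structure_columns_sum_to_one(self, default_world):
        f = build_factors(default_world[0], perspective="consumption")
        np.testing.assert_allclose(f.factors[3].sum(axis=0), 1.0, rtol=1e-8)

    def test_population_rescaling_is_compensated(self, default_world):
        # doubling population with per-capita level implicitly halved leaves
        # the factor product unchanged
        sl = default_world[0]
        pop = sl.mortality.P[:, 0]
        f1 = build_factors(sl, perspective="consumption")
        f2 = build_factors(sl, population=2 * pop, perspective="consumption")
        np.testing.assert_allclose(f1.product(), f2.product(), rtol=1e-10)

    def test_unknown_perspective_rejected(self, default_world):
        with pytest.raises(ValueError):
            build_factors(default_world[0], perspective="production")


class TestDriverRecovery:
    @pytest.mark.parametrize("factor", [
        "emission_factors", "energy_efficiency", "production_structure",
        "demand_structure", "demand_level", "population",
    ])
    def test_single_driver_attribution(self, default_world, factor):
        w = single_driver_world(default_world, factor, 1.25)
        f0 = build_factors(w[0], perspective="consumption")
        f1 = build_factors(w[1], perspective="consumption")
        r = two_polar_sda(f0, f1)
        assert abs(r.delta_total) > 0
        share = abs(r.contributions[factor]) / sum(abs(v) for v in r.contributions.values())
        assert share >= 0.99

    def test_kernel_change_shows_only_in_meteorology_term(self, default_world):
        w = single_driver_world(default_world, "kernel", 1.3)
        f0 = build_factors(w[0], perspective="consumption")
        f1 = build_factors(w[1], perspective="consumption")
        sda = two_polar_sda(f0, f1)
        hd = health_driver_decomposition(w, sda, f0, f1)
        socio = [hd.contributions[n] for n in sda.contributions]
        assert np.abs(socio).max() < 1e-9 * abs(hd.contributions["meteorology"])
        assert hd.contributions["meteorology"] != 0.0
        assert hd.contributions["mortality"] == pytest.approx(0.0, abs=1e-12)

    def test_mortality_change_shows_only_in_mortality_term(self, default_world):
        w = single_driver_world(default_world, "mortality", 1.3)
        f0 = build_factors(w[0], perspective="consumption")
        f1 = build_factors(w[1], perspective="consumption")
        hd = health_driver_decomposition(w, two_polar_sda(f0, f1), f0, f1)
        assert hd.contributions["mortality"] != 0.0
        assert hd.contributions["meteorology"] == pytest.approx(0.0, abs=1e-12)


class TestHealthDecomposition:
    def test_identical_years_give_all_zero(self, default_world):
        w = single_driver_world(default_world, "population", 1.0)
        f0 = build_factors(w[0], perspective="consumption")
        f1 = build_factors(w[1], perspective="consumption")
        hd = health_driver_decomposition(w, two_polar_sda(f0, f1), f0, f1)
        assert hd.delta_total == pytest.approx(0.0, abs=1e-12)
        assert all(abs(v) < 1e-12 for v in hd.contributions.values())

    def test_linear_limit_closes_exactly(self, default_world):
        f0 = build_factors(default_world[0], perspective="consumption")
        f1 = build_factors(default_world[1], perspective="consumption")
        sda = two_polar_sda(f0, f1)
        hd = health_driver_decomposition(
            default_world, sda, f0, f1,
            dose_response="linear", kernel_mode="fixed", mortality_mode="fixed",
        )
        assert abs(hd.residual) < 1e-8 * max(1.0, abs(hd.delta_total))
        assert hd.contributions["meteorology"] == 0.0
        assert hd.contributions["mortality"] == 0.0

    def test_default_residual_is_reported_not_reallocated(self, default_world):
        f0 = build_factors(default_world[0], perspective="consumption")
        f1 = build_factors(default_world[1], perspective="consumption")
        sda = two_polar_sda(f0, f1)
        hd = health_driver_decomposition(default_world, sda, f0, f1)
        assert hd.attributed + hd.residual == pytest.approx(hd.delta_total, rel=1e-12)
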