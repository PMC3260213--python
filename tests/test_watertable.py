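"""Equilibrium water-table solver: closed forms, oracles, and physics."""

import numpy as np
import pytest
from scipy.optimize import brentq

from hydrofowl.watertable import (
    Landscape,
    SolverError,
    WaterTableState,
    lateral_flux,
    mass_balance_residual,
    solve_equilibrium,
    transmissivity,
    wetland_mask,
)


def flat_landscape(shape=(8, 8), elevation=10.0, recharge=0.2, **kw):
    return Landscape(
        elevation=np.full(shape, elevation),
        recharge=np.full(shape, recharge),
        T0=kw.pop("T0", 1e6),
        f=kw.pop("f", 2.0),
        cell_length=kw.pop("cell_length", 1000.0),
        **kw,
    )


class TestLateralFlux:
    def setup_method(self):
        self.scape = flat_landscape()

    def test_equal_heads_zero(self):
        state = WaterTableState(np.full((8, 8), 1.0), 0, 0.0)
        assert lateral_flux(state, (0, 0), (0, 1), self.scape) == 0.0

    def test_unit_head_drop_at_surface(self):
        dwt = np.zeros((8, 8))
        scape = Landscape(
            elevation=np.zeros((8, 8)),
            recharge=np.zeros((8, 8)),
            T0=1e6,
            f=2.0,
            cell_length=1000.0,
        )
        scape.elevation[0, 0] = 1.0  # h difference of 1 m at zero depth
        state = WaterTableState(dwt, 0, 0.0)
        assert lateral_flux(state, (0, 0), (0, 1), scape) == pytest.approx(1e6)

    def test_depth_decay_one_efold(self):
        scape = flat_landscape()
        scape.elevation[0, 0] += 1.0
        shallow = WaterTableState(np.zeros((8, 8)), 0, 0.0)
        deep = WaterTableState(np.full((8, 8), scape.f), 0, 0.0)
        q0 = lateral_flux(shallow, (0, 0), (0, 1), scape)
        q1 = lateral_flux(deep, (0, 0), (0, 1), scape)
        assert q1 / q0 == pytest.approx(np.exp(-1.0))

    def test_antisymmetry(self):
        scape = flat_landscape()
        scape.elevation[2, 2] += 3.0
        state = WaterTableState(np.random.default_rng(0).random((8, 8)), 0, 0.0)
        assert lateral_flux(state, (2, 2), (2, 3), scape) == pytest.approx(
            -lateral_flux(state, (2, 3), (2, 2), scape)
        )

    def test_non_neighbours_rejected(self):
        state = WaterTableState(np.zeros((8, 8)), 0, 0.0)
        with pytest.raises(ValueError):
            lateral_flux(state, (0, 0), (1, 1), flat_landscape())


class TestEquilibrium:
    def test_flat_closed_basin_ponds(self):
        state = solve_equilibrium(flat_landscape())
        assert np.all(state.dwt == 0.0)

    def test_fixed_head_two_metres(self):
        fixed = np.zeros((8, 8), bool)
        fixed[0, 0] = True
        fd = np.zeros((8, 8))
        fd[0, 0] = 2.0
        scape = flat_landscape(recharge=0.0, fixed_head_mask=fixed, fixed_dwt=fd)
        state = solve_equilibrium(scape, tol=1e-5)
        assert np.abs(state.dwt - 2.0).max() < 1e-3  # within 1 mm everywhere

    def test_single_cell_against_root_finding_oracle(self):
        # one free cell beside one fixed-head cell: R*A = T(dbar)*(h - h_b)
        elev = np.array([[5.0, 5.0]])
        rech = np.array([[0.0, -0.05]])  # the free cell loses water to ET
        fixed = np.array([[True, False]])
        fd = np.array([[1.0, 0.0]])
        scape = Landscape(
            elevation=elev, recharge=rech, T0=1e5, f=2.0, cell_length=500.0,
            fixed_head_mask=fixed, fixed_dwt=fd, et_folding=1.0,
        )
        state = solve_equilibrium(scape, tol=1e-6)

        area = scape.cell_area
        h_b = 5.0 - 1.0

        def residual(d):
            h = 5.0 - d
            T = scape.T0 * np.exp(-(d + 1.0) / (2 * scape.f))
            r_eff = -0.05 * np.exp(-d / 1.0)
            return r_eff * area + T * (h_b - h)

        d_true = brentq(residual, 0.0, 50.0, xtol=1e-10)
        assert abs(state.dwt[0, 1] - d_true) < 1e-3

    def test_unbounded_drawdown_rejected(self):
        with pytest.raises(SolverError, match="unbounded"):
            solve_equilibrium(flat_landscape(recharge=-0.1))

    def test_nonconvergence_carries_residual(self):
        fixed = np.zeros((8, 8), bool)
        fixed[0, 0] = True
        scape = flat_landscape(recharge=0.0, fixed_head_mask=fixed,
                               fixed_dwt=np.where(fixed, 3.0, 0.0))
        with pytest.raises(SolverError) as err:
            solve_equilibrium(scape, tol=1e-12, max_iter=2)
        assert err.value.residual is not None

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        elev = rng.random((10, 10)) * 5.0
        fixed = np.zeros((10, 10), bool)
        fixed[0, :] = True
        scape = Landscape(elevation=elev, recharge=np.full((10, 10), 0.1),
                          T0=1e6, f=2.0, cell_length=1000.0,
                          fixed_head_mask=fixed, fixed_dwt=np.zeros((10, 10)))
        shifted = Landscape(elevation=elev + 100.0, recharge=scape.recharge,
                            T0=1e6, f=2.0, cell_length=1000.0,
                            fixed_head_mask=fixed, fixed_dwt=np.zeros((10, 10)))
        s1 = solve_equilibrium(scape, tol=1e-6)
        s2 = solve_equilibrium(shifted, tol=1e-6)
        assert np.abs(s1.dwt - s2.dwt).max() < 1e-6

    def test_more_recharge_never_deepens(self):
        rng = np.random.default_rng(5)
        elev = rng.random((8, 8)) * 4.0
        fixed = np.zeros((8, 8), bool)
        fixed[:, 0] = True
        common = dict(T0=5e5, f=2.0, cell_length=1000.0,
                      fixed_head_mask=fixed, fixed_dwt=np.zeros((8, 8)))
        lo = Landscape(elevation=elev, recharge=np.full((8, 8), 0.02), **common)
        hi = Landscape(elevation=elev, recharge=np.full((8, 8), 0.1), **common)
        d_lo = solve_equilibrium(lo, tol=1e-6).dwt
        d_hi = solve_equilibrium(hi, tol=1e-6).dwt
        assert np.all(d_hi <= d_lo + 1e-4)

    def test_valley_is_wetter_on_v_transect(self):
        n = 21
        x = np.abs(np.arange(n) - n // 2).astype(float)
        elev = np.tile(2.0 * x, (5, 1))  # V-shaped valley along the middle column
        fixed = np.zeros((5, n), bool)
        fixed[:, n // 2] = True  # river at the valley axis
        scape = Landscape(elevation=elev, recharge=np.full((5, n), 0.1),
                          T0=1e6, f=2.0, cell_length=1000.0,
                          fixed_head_mask=fixed,
                          fixed_dwt=np.where(fixed, 0.5, 0.0), T_min=1e2)
        state = solve_equilibrium(scape, tol=1e-5)
        valley = state.dwt[:, n // 2].mean()
        ridge = state.dwt[:, [0, -1]].mean()
        assert valley <= ridge

    def test_dwt_never_negative(self):
        rng = np.random.default_rng(9)
        elev = rng.random((12, 12)) * 8.0
        fixed = np.zeros((12, 12), bool)
        fixed[0, 0] = True
        scape = Landscape(elevation=elev, recharge=rng.normal(0.05, 0.05, (12, 12)),
                          T0=1e6, f=2.0, cell_length=1000.0,
                          fixed_head_mask=fixed, fixed_dwt=np.zeros((12, 12)),
                          T_min=1e2)
        state = solve_equilibrium(scape, tol=1e-4)
        assert np.all(state.dwt >= 0.0)


class TestWetlandMask:
    def test_threshold_and_boundary(self):
        dwt = np.array([[0.5, 1.0, 1.5]])
        mask = wetland_mask(dwt)
        assert mask.tolist() == [[True, True, False]]  # <= 1.0 m convention

    def test_all_dry(self):
        assert not wetland_mask(np.full((4, 4), 10.0)).any()

    def test_nodata_propagates(self):
        dwt = np.array([[0.5, np.nan]])
        mask = wetland_mask(dwt)
        assert bool(mask[0, 0]) and np.ma.is_masked(mask[0, 1])

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            wetland_mask(np.zeros((2, 2)), threshold=-1.0)


class TestMassBalance:
    def make_case(self):
        rng = np.random.default_rng(7)
        elev = rng.random((10, 10)) * 3.0
        fixed = np.zeros((10, 10), bool)
        fixed[:, 0] = True
        return Landscape(elevation=elev, recharge=np.full((10, 10), 0.08),
                         T0=1e6, f=2.0, cell_length=1000.0,
                         fixed_head_mask=fixed, fixed_dwt=np.zeros((10, 10)),
                         T_min=1e2)

    def test_converged_case_closes(self):
        scape = self.make_case()
        state = solve_equilibrium(scape, tol=1e-5)
        assert mass_balance_residual(state, scape) < 0.01

    def test_zero_recharge_flat_case_is_exact(self):
        fixed = np.zeros((6, 6), bool)
        fixed[0, 0] = True
        scape = flat_landscape(shape=(6, 6), recharge=0.0,
                               fixed_head_mask=fixed,
                               fixed_dwt=np.where(fixed, 2.0, 0.0))
        state = solve_equilibrium(scape, tol=1e-6)
        assert mass_balance_residual(state, scape) < 1e-6

    def test_residual_shrinks_with_tolerance(self):
        scape = self.make_case()
        residuals = [
            mass_balance_residual(solve_equilibrium(scape, tol=t), scape)
            for t in (1e-2, 1e-4, 1e-6)
        ]
        assert residuals[2] <= residuals[0] + 1e-12


class TestTransmissivity:
    def test_exponential_decay(self):
        scape = flat_landscape()
        assert transmissivity(0.0, scape) == pytest.approx(scape.T0)
        assert transmissivity(scape.f, scape) == pytest.approx(scape.T0 * np.exp(-1))

    def test_invalid_landscape_params(self):
        with pytest.raises(ValueError):
            flat_landscape(T0=-1.0)
        with pytest.raises(ValueError):
            flat_landscape(f=0.0)
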