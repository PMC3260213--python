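"""Gridded equilibrium depth-to-water-table (DWT) solver.

The water table sits where climate-driven recharge (precipitation minus
evapotranspiration) balances lateral groundwater drainage toward rivers
and the coast.  This module solves that balance on a regular grid:

* each cell carries a hydraulic head ``h = elevation - dwt``;
* lateral flow between 4-neighbours follows Darcy's law with a
  transmissivity that decays exponentially with water-table depth,
  ``T(d) = T0 * exp(-d / f)`` (deep water tables sit in poorly conductive
  material, so drainage shuts down with depth);
* river/ocean cells hold a fixed, prescribed head;
* where the balance would push the water table above the land surface the
  depth is clipped to zero — ponded cells shed the excess (wetlands, lakes).

The solver starts from a water table at the surface and relaxes cell heads
(red-black Gauss–Seidel with under-relaxation) until no cell's depth moves
by more than a tolerance, 1 mm by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SolverError(RuntimeError):
    """Raised when the equilibrium iteration cannot complete."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class Landscape:
    """Inputs of the equilibrium water-table problem.

    Parameters
    ----------
    elevation:
        Land-surface elevation per cell, metres.
    recharge:
        Net recharge per cell, metres/year (may be negative where
        evapotranspiration exceeds precipitation).
    fixed_head_mask:
        Boolean; True marks river/ocean cells whose water-table depth is
        prescribed and held exactly.
    fixed_dwt:
        Prescribed depth (m) at fixed-head cells; ignored elsewhere.
    T0:
        Transmissivity at zero depth, m^2/year.
    f:
        e-folding depth of the transmissivity decay, metres.
    cell_length:
        Cell edge length, metres (square cells).
    et_folding:
        e-folding depth (m) of the groundwater-evapotranspiration shutoff:
        the negative part of recharge is an ET demand drawn from the water
        table, which decays as ``exp(-dwt / et_folding)`` once the table
        drops out of reach.  Defaults to ``f``.  Without this shutoff a
        net-negative cell has no equilibrium (its depth runs away as the
        transmissivity decays).
    """

    elevation: np.ndarray
    recharge: np.ndarray
    T0: float
    f: float
    cell_length: float
    fixed_head_mask: np.ndarray | None = None
    fixed_dwt: np.ndarray | None = None
    et_folding: float | None = None
    #: residual deep transmissivity (m^2/yr): flow through the permeable
    #: basement that persists however deep the water table sits; keeps the
    #: equilibrium finite in steep terrain.  0 = purely exponential decay.
    T_min: float = 0.0

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.recharge = np.asarray(self.recharge, dtype=float)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be a 2-D array")
        if self.recharge.shape != self.elevation.shape:
            raise ValueError("recharge shape must match elevation")
        if self.T0 <= 0 or self.f <= 0:
            raise ValueError("T0 and f must be positive")
        if self.cell_length <= 0:
            raise ValueError("cell_length must be positive")
        if self.fixed_head_mask is None:
            self.fixed_head_mask = np.zeros(self.elevation.shape, dtype=bool)
        else:
            self.fixed_head_mask = np.asarray(self.fixed_head_mask, dtype=bool)
            if self.fixed_head_mask.shape != self.elevation.shape:
                raise ValueError("fixed_head_mask shape must match elevation")
        if self.fixed_dwt is None:
            self.fixed_dwt = np.zeros(self.elevation.shape, dtype=float)
        else:
            self.fixed_dwt = np.asarray(self.fixed_dwt, dtype=float)
            if self.fixed_dwt.shape != self.elevation.shape:
                raise ValueError("fixed_dwt shape must match elevation")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def cell_area(self) -> float:
        return self.cell_length ** 2

    def effective_recharge(self, dwt: np.ndarray) -> np.ndarray:
        """Depth-dependent net recharge (m/yr): ET demand decays with depth."""
        f_et = self.et_folding if self.et_folding is not None else self.f
        gain = np.clip(self.recharge, 0.0, None)
        demand = np.clip(-self.recharge, 0.0, None)
        return gain - demand * np.exp(-np.clip(dwt, 0.0, None) / f_et)


@dataclass
class WaterTableState:
    """Converged (or partial) solution of the equilibrium problem."""

    dwt: np.ndarray  # metres below surface, >= 0
    iterations: int
    max_delta: float  # last sweep's largest per-cell |change in dwt|, metres

    def head(self, landscape: Landscape) -> np.ndarray:
        return landscape.elevation - self.dwt


def transmissivity(depth: np.ndarray | float, landscape: Landscape) -> np.ndarray | float:
    """Depth-decaying transmissivity T(d) = T0 * exp(-d/f) + T_min."""
    return (
        landscape.T0 * np.exp(-np.asarray(depth, dtype=float) / landscape.f)
        + landscape.T_min
    )


def lateral_flux(
    state: WaterTableState,
    cell_i: tuple[int, int],
    cell_j: tuple[int, int],
    landscape: Landscape,
) -> float:
    """Volumetric flow (m^3/year) from cell i to its 4-neighbour j.

    ``Q_ij = T(mean depth) * (h_i - h_j) / dx * w``; antisymmetric in i, j.
    """
    ri, ci = cell_i
    rj, cj = cell_j
    if abs(ri - rj) + abs(ci - cj) != 1:
        raise ValueError(f"{cell_i} and {cell_j} are not 4-neighbours")
    h = state.head(landscape)
    d_mean = 0.5 * (state.dwt[ri, ci] + state.dwt[rj, cj])
    T = transmissivity(d_mean, landscape)
    return float(T * (h[ri, ci] - h[rj, cj]))  # w / dx = 1 for square cells


def _edge_conductance(dwt: np.ndarray, landscape: Landscape, axis: int) -> np.ndarray:
    """Conductance T(d_mean)*w/dx on edges along *axis* (w/dx = 1, square cells)."""
    if axis == 0:
        d_mean = 0.5 * (dwt[:-1, :] + dwt[1:, :])
    else:
        d_mean = 0.5 * (dwt[:, :-1] + dwt[:, 1:])
    return landscape.T0 * np.exp(-d_mean / landscape.f) + landscape.T_min


def _net_inflow(head: np.ndarray, dwt: np.ndarray, landscape: Landscape) -> np.ndarray:
    """Net lateral volumetric inflow (m^3/yr) into every cell."""
    net = np.zeros_like(head)
    cv = _edge_conductance(dwt, landscape, axis=0)  # vertical edges (between rows)
    fv = cv * (head[:-1, :] - head[1:, :])  # flow from row r to row r+1
    net[:-1, :] -= fv
    net[1:, :] += fv
    ch = _edge_conductance(dwt, landscape, axis=1)
    fh = ch * (head[:, :-1] - head[:, 1:])
    net[:, :-1] -= fh
    net[:, 1:] += fh
    return net


def solve_equilibrium(
    landscape: Landscape,
    tol: float = 0.001,
    max_iter: int = 50_000,
    relax: float = 0.5,
    callback=None,
) -> WaterTableState:
    """Iterate the water table to equilibrium from the land surface.

    Damped Newton iteration on the head balance: each step linearizes the
    per-cell residual (effective recharge plus net lateral inflow through
    the depth-decaying conductances) around the current heads, solves the
    sparse linear system for a head correction, scales it by ``relax``,
    caps it at two transmissivity e-folds (so the linearization never runs
    far ahead of the conductances) and projects heads back to the land
    surface where the balance would pond water.  Iteration stops when no
    cell's depth moved more than ``tol`` (metres, 1 mm by default).
    Deterministic given inputs.

    A landscape with no fixed-head cell is a closed basin: its lowest cell
    is anchored at the surface (water accumulating in a closed basin ponds
    from the bottom up), which also pins the otherwise floating head level.

    Raises
    ------
    SolverError
        On non-convergence within ``max_iter`` iterations, or when the
        problem is unbounded (net-negative recharge with no fixed-head
        outlet).
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.linalg import spsolve

    if not 0 < relax <= 1:
        raise ValueError("relax must be in (0, 1]")
    fixed = landscape.fixed_head_mask.copy()
    area = landscape.cell_area
    z = landscape.elevation
    f = landscape.f
    f_et = landscape.et_folding if landscape.et_folding is not None else f
    fixed_head = z - landscape.fixed_dwt
    if not fixed.any():
        if float(np.sum(landscape.recharge)) < 0:
            raise SolverError(
                "unbounded drawdown: net-negative recharge with no fixed-head boundary"
            )
        # closed basin: anchor the lowest cell at the surface
        r0, c0 = np.unravel_index(int(np.argmin(z)), z.shape)
        fixed[r0, c0] = True
        fixed_head[r0, c0] = z[r0, c0]

    free = ~fixed
    n_rows, n_cols = landscape.shape
    free_index = -np.ones(landscape.shape, dtype=int)
    free_index[free] = np.arange(int(free.sum()))
    n_free = int(free.sum())
    if n_free == 0:
        dwt0 = np.maximum(z - fixed_head, 0.0)
        return WaterTableState(dwt=dwt0, iterations=0, max_delta=0.0)

    # static edge structure: every 4-neighbour pair once, as (a, b)
    rr, cc = np.meshgrid(np.arange(n_rows - 1), np.arange(n_cols), indexing="ij")
    va = (rr.ravel(), cc.ravel())
    vb = (rr.ravel() + 1, cc.ravel())
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols - 1), indexing="ij")
    ha = (rr.ravel(), cc.ravel())
    hb = (rr.ravel(), cc.ravel() + 1)
    ea_r = np.concatenate([va[0], ha[0]])
    ea_c = np.concatenate([va[1], ha[1]])
    eb_r = np.concatenate([vb[0], hb[0]])
    eb_c = np.concatenate([vb[1], hb[1]])
    fa = free_index[ea_r, ea_c]
    fb = free_index[eb_r, eb_c]
    a_free = fa >= 0
    b_free = fb >= 0
    ab_rows = np.concatenate([fa[a_free & b_free], fb[a_free & b_free]])
    ab_cols = np.concatenate([fb[a_free & b_free], fa[a_free & b_free]])
    diag_idx = np.arange(n_free)

    head = z.copy()
    head[~free] = fixed_head[~free]
    gain = np.clip(landscape.recharge, 0.0, None) * area
    demand = np.clip(-landscape.recharge, 0.0, None) * area
    step_cap = 2.0 * f
    max_delta = np.inf

    def balance_parts(head_arr):
        """Depths, conductances, head differences and residual at given heads."""
        dwt = np.maximum(z - head_arr, 0.0)
        et_decay = np.exp(-dwt / f_et)
        recharge_volume = gain - demand * et_decay
        g = np.exp(-dwt / (2.0 * f))  # c_ab = T0 * g_a * g_b + T_min
        # tiny floor keeps very deep cells numerically attached to the system
        c = landscape.T0 * g[ea_r, ea_c] * g[eb_r, eb_c] + max(
            landscape.T_min, landscape.T0 * 1e-12
        )
        dh = head_arr[eb_r, eb_c] - head_arr[ea_r, ea_c]  # h_b - h_a
        F = recharge_volume[free].copy()
        np.add.at(F, fa[a_free], (c * dh)[a_free])
        np.add.at(F, fb[b_free], (-c * dh)[b_free])
        return dwt, et_decay, recharge_volume, c, dh, F

    def merit_norm(head_arr, F):
        """Residual norm of the ponding variational inequality: a cell held
        at the surface may legitimately shed a positive excess."""
        ponded = head_arr[free] >= z[free]
        m = np.where(ponded, np.minimum(F, 0.0), F)
        return float(np.linalg.norm(m))

    prev_clamped: np.ndarray | None = None
    for iteration in range(1, max_iter + 1):
        dwt, et_decay, recharge_volume, c, dh, F = balance_parts(head)
        active = dwt > 0.0  # depth responds to head only below the surface

        # active set: ponded cells shedding a non-negative excess are clamped
        # to the surface and leave the system for this iteration
        ponded_free = head[free] >= z[free] - 1e-12
        clamped = ponded_free & (F >= 0.0)
        solve_mask_grid = free.copy()
        solve_mask_grid[free] = ~clamped
        n_solve = int((~clamped).sum())

        if n_solve == 0:
            if prev_clamped is not None and np.array_equal(clamped, prev_clamped):
                dwt = np.maximum(z - head, 0.0)
                dwt[~free] = np.maximum((z - fixed_head), 0.0)[~free]
                return WaterTableState(dwt=dwt, iterations=iteration, max_delta=0.0)
            prev_clamped = clamped
            continue

        solve_index = -np.ones(landscape.shape, dtype=int)
        solve_index[solve_mask_grid] = np.arange(n_solve)
        sa = solve_index[ea_r, ea_c]
        sb = solve_index[eb_r, eb_c]
        sa_in = sa >= 0
        sb_in = sb >= 0
        both = sa_in & sb_in

        # Jacobian dF/dh over the solved cells
        act_a = active[ea_r, ea_c].astype(float)
        act_b = active[eb_r, eb_c].astype(float)
        # d c / d h = (c - T_min)/(2f) when that endpoint's depth responds
        c_decay = np.clip(c - landscape.T_min, 0.0, None)
        dc_da = c_decay / (2.0 * f) * act_a
        dc_db = c_decay / (2.0 * f) * act_b
        diag = np.zeros(n_solve)
        # ET shutoff derivative: d(recharge)/dh = -demand * exp(-d/f_et)/f_et
        diag[:] = (-demand * et_decay / f_et * active)[solve_mask_grid]
        np.add.at(diag, sa[sa_in], (dc_da * dh - c)[sa_in])
        np.add.at(diag, sb[sb_in], (-dc_db * dh - c)[sb_in])
        off = np.concatenate([(c + dc_db * dh)[both], (c - dc_da * dh)[both]])
        rows = np.concatenate([sa[both], sb[both], np.arange(n_solve)])
        cols = np.concatenate([sb[both], sa[both], np.arange(n_solve)])
        J = coo_matrix(
            (np.concatenate([off, diag]), (rows, cols)), shape=(n_solve, n_solve)
        ).tocsr()
        F_solve = F[~clamped]
        with np.errstate(all="ignore"):
            delta_h = spsolve(J, -F_solve)
        if not np.all(np.isfinite(delta_h)):
            raise SolverError(
                "singular head system: free cells disconnected from any fixed head"
            )

        step = np.clip(relax * delta_h, -step_cap, step_cap)
        # backtracking line search on the complementarity residual
        merit0 = merit_norm(head, F)
        scale = 1.0
        h_try = head.copy()
        for _ in range(20):
            h_try[solve_mask_grid] = np.minimum(
                head[solve_mask_grid] + scale * step, z[solve_mask_grid]
            )
            _, _, _, _, _, F_try = balance_parts(h_try)
            if merit_norm(h_try, F_try) <= merit0 * (1.0 - 1e-4 * scale) or merit0 == 0.0:
                break
            scale *= 0.5
        max_delta = float(
            np.max(np.abs(np.maximum(z - h_try, 0.0)[free] - dwt[free]))
        )
        head = h_try
        if callback is not None:
            callback(iteration, max_delta, float(np.max(np.abs(delta_h))),
                     int(clamped.sum()), scale)
        converged = (
            float(np.max(np.abs(delta_h))) < tol
            and prev_clamped is not None
            and np.array_equal(clamped, prev_clamped)
        )
        prev_clamped = clamped
        if converged:
            dwt = np.maximum(z - head, 0.0)
            dwt[~free] = np.maximum((z - fixed_head), 0.0)[~free]
            return WaterTableState(dwt=dwt, iterations=iteration, max_delta=max_delta)

    raise SolverError(
        f"no convergence after {max_iter} iterations (max |d dwt| = {max_delta:.3g} m)",
        residual=max_delta,
    )


def wetland_mask(dwt_layer: np.ndarray, threshold: float = 1.0) -> np.ma.MaskedArray:
    """Wetland where dwt <= threshold (metres); NaN nodata propagates as mask."""
    if threshold < 0:
        raise ValueError("wetland threshold must be non-negative")
    layer = np.ma.masked_invalid(np.asarray(dwt_layer, dtype=float))
    return layer <= threshold


def mass_balance_residual(state: WaterTableState, landscape: Landscape) -> float:
    """Relative closure error of the converged water balance.

    Sums recharge over free, non-ponded cells, subtracts net outflow into
    fixed-head cells and the excess shed by ponded cells, and normalizes by
    the total absolute recharge.  Near zero at equilibrium.
    """
    fixed = landscape.fixed_head_mask
    free = ~fixed
    area = landscape.cell_area
    head = state.head(landscape)
    net_in = _net_inflow(head, state.dwt, landscape)
    recharge_volume = landscape.effective_recharge(state.dwt) * area

    ponded = free & (state.dwt <= 0)
    non_ponded = free & ~ponded
    total_recharge = float(np.sum(recharge_volume[non_ponded]))
    # water leaving the free domain shows up as net lateral inflow at fixed
    # cells; lateral water reaching an already-ponded cell is shed likewise
    boundary_outflow = float(np.sum(net_in[fixed]))
    ponding_excess = float(np.sum(net_in[ponded]))
    denom = float(np.sum(np.abs(recharge_volume[free])))
    num = abs(total_recharge - boundary_outflow - ponding_excess)
    if denom == 0.0:
        # no recharge anywhere: any leftover flux is numerical noise;
        # report it relative to the conductance flux scale (T0 x 1 m drop)
        return num / landscape.T0
    return num / denom
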