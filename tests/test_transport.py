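"""Forward-model tests: grids, solute transport, pigment tracers."""

import numpy as np
import pytest

from bioturb import (
    ExchangeField,
    SolidTracerState,
    SoluteState,
    TransportParameters,
    build_grid,
    exchange_budget,
    solve_pigments,
    solve_solute,
    steady_state_pigments,
    tortuosity_correction,
    window_profile,
)


class TestBuildGrid:
    def test_uniform_grid_arithmetic(self):
        g = build_grid(40, 80, 0.4)
        assert g.n_cells == 80
        assert np.allclose(g.cell_widths, 0.5)
        assert np.allclose(g.cell_centers, np.arange(80) * 0.5 + 0.25)
        assert g.cell_centers[0] == 0.25 and g.cell_centers[-1] == 39.75

    @pytest.mark.parametrize(
        "depth,n,phi",
        [(40, 1, 0.4), (40, 3, 0.4), (-1, 10, 0.4), (0, 10, 0.4), (10, 10, 1.0), (10, 10, 0.0)],
    )
    def test_invalid_arguments(self, depth, n, phi):
        with pytest.raises(ValueError):
            build_grid(depth, n, phi)

    def test_porosity_profile(self):
        phi = np.linspace(0.5, 0.35, 20)
        g = build_grid(10, 20, phi)
        assert np.allclose(g.porosity, phi)


class TestSoluteModel:
    def test_equilibrium_fixed_point(self, grid):
        """C identically C_ow is stationary for any exchange field."""
        rng = np.random.default_rng(0)
        ex = ExchangeField(rng.uniform(0, 2, grid.n_cells), rng.uniform(0, 1, grid.n_cells))
        init = SoluteState("DIC", np.full(grid.n_cells, 2.2), 2.2)
        out = solve_solute(grid, TransportParameters(), ex, init, 30, [10, 30])
        for s in out:
            assert np.allclose(s.concentration, 2.2, rtol=1e-10)

    def test_nonlocal_relaxation_rate(self, grid):
        """With D_s = 0 and constant alpha, |C - C_ow| decays at rate alpha.

        Log-linear fit of the simulated decay must match the closed form
        exp(-a t) within 1% at dt = 0.01/a.
        """
        a = 0.5
        ex = ExchangeField(np.full(grid.n_cells, a), np.zeros(grid.n_cells))
        params = TransportParameters(molecular_diffusivity=0.0)
        init = SoluteState("DIC", np.full(grid.n_cells, 5.0), 2.0)
        times = [2.0, 4.0, 6.0, 8.0]
        out = solve_solute(grid, params, ex, init, 10, times, dt=0.01 / a)
        dev = [np.max(np.abs(s.concentration - 2.0)) for s in out]
        rate = -np.polyfit(times, np.log(dev), 1)[0]
        assert abs(rate / a - 1) < 0.01
        # monotone relaxation
        assert all(d2 <= d1 + 1e-12 for d1, d2 in zip(dev, dev[1:]))

    def test_diffusion_decay_steady_state(self, fine_grid):
        """Steady state of diffusion + first-order sink matches C0 exp(-x sqrt(k/Ds)).

        Fixed-value boundaries at both ends make the exponential the exact
        solution of the finite column; cell-wise error < 1% at 0.25 cm.
        """
        g = fine_grid
        d0 = 1.0
        d_s = tortuosity_correction(d0, g.porosity[:1])[0]
        k = 0.16 * d_s  # decay length sqrt(Ds/k) = 2.5 cm
        kappa = np.sqrt(k / d_s)
        params = TransportParameters(molecular_diffusivity=d0, first_order_sink=k)
        c_ow = 2.0
        init = SoluteState("DIC", np.full(g.n_cells, c_ow), c_ow)
        out = solve_solute(
            g, params, ExchangeField.zero(g), init, 4000, [4000], dt=2.0,
            bottom_boundary="fixed", bottom_value=c_ow * np.exp(-40 * kappa),
        )
        analytic = c_ow * np.exp(-kappa * g.cell_centers)
        assert np.max(np.abs(out[0].concentration / analytic - 1)) < 0.01

    def test_grid_convergence_order(self):
        """Halving the cell width reduces the steady-state error at order >= 1.8."""
        errs = []
        for n in (80, 160):
            g = build_grid(40, n, 0.4)
            d_s = tortuosity_correction(1.0, g.porosity[:1])[0]
            k = 0.16 * d_s
            kappa = np.sqrt(k / d_s)
            params = TransportParameters(molecular_diffusivity=1.0, first_order_sink=k)
            init = SoluteState("DIC", np.full(g.n_cells, 2.0), 2.0)
            out = solve_solute(
                g, params, ExchangeField.zero(g), init, 4000, [4000], dt=2.0,
                bottom_boundary="fixed", bottom_value=2.0 * np.exp(-40 * kappa),
            )
            analytic = 2.0 * np.exp(-kappa * g.cell_centers)
            errs.append(np.max(np.abs(out[0].concentration / analytic - 1)))
        order = np.log2(errs[0] / errs[1])
        assert order >= 1.8

    def test_closed_system_conservation(self, fine_grid):
        """No-flux, no-reaction columns conserve phi-weighted mass to < 1e-8."""
        g = fine_grid
        rng = np.random.default_rng(1)
        init = SoluteState("X", rng.uniform(1, 3, g.n_cells), 0.0)
        mass0 = np.sum(g.porosity * g.cell_widths * init.concentration)
        out = solve_solute(
            g, TransportParameters(), ExchangeField.zero(g), init,
            100, [100], dt=0.01, top_boundary="no_flux",
        )
        mass1 = np.sum(g.porosity * g.cell_widths * out[0].concentration)
        assert abs(mass1 / mass0 - 1) < 1e-8

    def test_nan_input_rejected(self, grid):
        init = SoluteState("DIC", np.full(grid.n_cells, np.nan), 2.0)
        with pytest.raises(ValueError):
            solve_solute(grid, TransportParameters(), ExchangeField.zero(grid), init, 1, [1])


class TestPigmentModel:
    def test_null_forcing(self, grid):
        """Zero initial state and zero surface flux stay identically zero."""
        init = SolidTracerState(np.zeros(grid.n_cells), np.zeros(grid.n_cells))
        out = solve_pigments(grid, TransportParameters(), init, 50, [10, 50])
        for s in out:
            assert np.all(s.chl_a == 0) and np.all(s.pheopigment == 0)

    def test_steady_efolding_length(self, grid):
        """Steady chl profile decays over sqrt(D / k_chl) under constant D."""
        d, k = 2.0, 0.05
        params = TransportParameters(
            biodiffusion_physical=d, chl_decay=k, pheo_decay=0.005, surface_chl_flux=1.0
        )
        ss = steady_state_pigments(grid, params)
        sl = slice(10, 60)
        slope = np.polyfit(grid.cell_centers[sl], np.log(ss.chl_a[sl]), 1)[0]
        assert abs((-1 / slope) / np.sqrt(d / k) - 1) < 0.01

    def test_transient_approaches_steady_state(self, grid):
        params = TransportParameters(
            biodiffusion_physical=2.0, chl_decay=0.05, pheo_decay=0.01,
            surface_chl_flux=1.0,
        )
        init = SolidTracerState(np.zeros(grid.n_cells), np.zeros(grid.n_cells))
        out = solve_pigments(grid, params, init, 3000, [3000], dt=1.0)
        ss = steady_state_pigments(grid, params)
        assert np.allclose(out[0].chl_a, ss.chl_a, rtol=1e-3, atol=1e-9)

    def test_pure_mixing_conserves_both_tracers(self, grid):
        """k_chl = k_pheo = 0, no flux: depth-integrated mass is conserved."""
        rng = np.random.default_rng(2)
        params = TransportParameters(
            biodiffusion_physical=1.0, chl_decay=0.0, pheo_decay=0.0, surface_chl_flux=0.0
        )
        init = SolidTracerState(rng.uniform(0, 5, grid.n_cells), rng.uniform(0, 2, grid.n_cells))
        m0 = init.chl_a @ grid.cell_widths, init.pheopigment @ grid.cell_widths
        out = solve_pigments(grid, params, init, 100, [100], dt=0.01)
        m1 = out[0].chl_a @ grid.cell_widths, out[0].pheopigment @ grid.cell_widths
        assert abs(m1[0] / m0[0] - 1) < 1e-8
        assert abs(m1[1] / m0[1] - 1) < 1e-8

    def test_chl_mass_flows_to_pheopigment(self, grid):
        """With yield 1 and no pheo decay, total pigment mass is conserved."""
        params = TransportParameters(
            biodiffusion_physical=1.0, chl_decay=0.1, pheo_decay=0.0,
            chl_to_pheo_yield=1.0, surface_chl_flux=0.0,
        )
        init = SolidTracerState(np.full(grid.n_cells, 2.0), np.zeros(grid.n_cells))
        out = solve_pigments(grid, params, init, 30, [30], dt=0.005)
        total0 = 2.0 * grid.depth_max
        total1 = (out[0].chl_a + out[0].pheopigment) @ grid.cell_widths
        # explicit coupling is first-order in dt; tolerance reflects dt=0.005
        assert abs(total1 / total0 - 1) < 1e-3


class TestExchangeBudget:
    def test_zero_at_equilibrium(self, grid):
        state = SoluteState("DIC", np.full(grid.n_cells, 2.0), 2.0)
        ex = ExchangeField(np.ones(grid.n_cells), np.ones(grid.n_cells))
        assert exchange_budget(grid, state, ex) == 0.0

    def test_single_cell_arithmetic(self):
        g = build_grid(4, 4, 0.5)
        conc = np.full(4, 1.0)
        conc[0] = 0.0  # C_ow - C = 1 in the first cell only
        state = SoluteState("DIC", conc, 1.0)
        alpha = np.zeros(4)
        alpha[0] = 2.0
        ex = ExchangeField(alpha, np.zeros(4))
        # phi * alpha * (C_ow - C) * width = 0.5 * 2 * 1 * 1
        assert exchange_budget(g, state, ex) == pytest.approx(1.0, abs=1e-14)

    def test_operator_consistency(self, grid):
        """The budget equals the mass added by a diffusion-free implicit step."""
        rng = np.random.default_rng(3)
        ex = ExchangeField(rng.uniform(0, 2, grid.n_cells), rng.uniform(0, 1, grid.n_cells))
        init = SoluteState("DIC", rng.uniform(0, 4, grid.n_cells), 2.0)
        params = TransportParameters(molecular_diffusivity=0.0)
        dt = 0.05
        out = solve_solute(grid, params, ex, init, dt, [dt], dt=dt, top_boundary="no_flux")
        mass_change = (
            grid.porosity * grid.cell_widths @ (out[0].concentration - init.concentration)
        )
        # implicit step: change equals dt * budget evaluated at the NEW state
        budget_new = exchange_budget(grid, out[0], ex)
        assert abs(mass_change - dt * budget_new) < 1e-10

    def test_length_mismatch(self, grid):
        state = SoluteState("DIC", np.full(grid.n_cells, 1.0), 1.0)
        ex = ExchangeField(np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            exchange_budget(grid, state, ex)


def test_window_profile_edges(grid):
    w = window_profile(grid, 2.0, 10.0, 20.0, edge_width=1.0)
    x = grid.cell_centers
    assert np.all(w[(x >= 10) & (x <= 20)] == 2.0)
    assert np.all(w[(x < 9) | (x > 21)] == 0.0)
    assert np.all((w >= 0) & (w <= 2.0))
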