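"""Forward porewater model: diffusion + nonlocal exchange with seawater.

Builds a 40 cm sand column, applies surface-intensified physical
exchange plus a lugworm bioirrigation window, lets DIC accumulate from
mineralization for four weeks, and audits the exchange mass balance.
"""

import numpy as np

from bioturb import (
    ExchangeField,
    SoluteState,
    TransportParameters,
    build_grid,
    exchange_budget,
    exponential_profile,
    solve_solute,
    window_profile,
)

grid = build_grid(depth_max=40.0, n_cells=80, porosity=0.4)
exchange = ExchangeField(
    alpha_physical=exponential_profile(grid, 0.3, 4.0),   # 0.3/d, e-folding 4 cm
    alpha_biological=window_profile(grid, 0.15, 8.0, 18.0),  # burrow zone
)
params = TransportParameters(molecular_diffusivity=1.0, production=0.25)  # mM/d DIC source
initial = SoluteState("DIC", np.full(grid.n_cells, 2.2), overlying_water_conc=2.2)

states = solve_solute(grid, params, exchange, initial, duration=28.0, output_times=[14.0, 28.0])
for s in states:
    i5, i15, i30 = np.searchsorted(grid.cell_centers, [5, 15, 30])
    print(
        f"day {s.time:4.0f}: DIC at 5/15/30 cm = "
        f"{s.concentration[i5]:.2f} / {s.concentration[i15]:.2f} / "
        f"{s.concentration[i30]:.2f} mM"
    )
budget = exchange_budget(grid, states[-1], exchange)
print(f"net exchange flux at day 28: {budget:.3f} mM cm/day (negative = DIC escaping)")
print(
    "DIC builds up below the irrigated zone; exchange keeps the top and the\n"
    "burrow window close to the seawater value of 2.2 mM."
)
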