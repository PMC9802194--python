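"""Particle mixing from pigment tracers, and the feeding-intensity proxy.

Fits physical (D_P) and biological (D_B) biodiffusion to steady chl a /
pheopigment profiles, then computes the feeding-intensity profile F_B
from sand fractions: the coarse-sand enrichment left behind where worms
selectively ingest fine particles.
"""

import numpy as np

from bioturb import (
    ScenarioConfig,
    feeding_intensity,
    fit_particle_mixing,
    generate_pigments_grainsize,
)

config = ScenarioConfig(seed=7)
data = generate_pigments_grainsize(config)

fit = fit_particle_mixing(data["observations"], config.pigment_config(), seed=0)
print(
    f"particle mixing: d_P = {fit.parameters['d_P']:.2f} cm^2/d "
    f"(truth {config.d_p}), d_B = {fit.parameters['d_B']:.2f} cm^2/d "
    f"(truth {config.d_b})"
)

f_b = feeding_intensity(data["sand_bioturbated"], data["sand_control"])
peak = np.argmax(f_b)
print(
    f"feeding intensity peaks at {data['sand_depths'][peak]:.1f} cm "
    f"with F_B = {f_b[peak]:.2f} (planted bump {config.feeding_bump} over "
    f"{config.feeding_window[0]:g}-{config.feeding_window[1]:g} cm)"
)
print(
    "D_B and the F_B peak both sit in the worms' feeding depth: biological\n"
    "particle mixing and selective feeding act on the same subsurface layer."
)
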