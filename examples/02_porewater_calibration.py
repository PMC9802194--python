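"""Two-stage porewater calibration: physical mixing, then bioirrigation.

Generates noisy synthetic DIC/sulfate profiles for a defaunated and a
refaunated treatment, fits alpha_P(x) to the defaunated data, then fits
the bioirrigation window on the refaunated data with alpha_P held fixed
-- the attribution logic of the two-treatment experiment.
"""

from bioturb import (
    ScenarioConfig,
    build_grid,
    fit_bioirrigation,
    fit_physical_porewater,
    generate_geochem,
)

config = ScenarioConfig(seed=42)
data = generate_geochem(config)
defaunated = [o for o in data["observations"] if o.treatment == "defaunated"]
refaunated = [o for o in data["observations"] if o.treatment == "refaunated"]

# fit on a coarser grid than the generator (1 cm cells)
fit_config = config.porewater_config(grid=build_grid(40.0, 40, config.porosity))

physical = fit_physical_porewater(defaunated, fit_config, seed=0)
print(
    f"physical exchange:  a_P = {physical.parameters['a_P']:.3f}/d "
    f"(truth {config.a_p}), L_P = {physical.parameters['L_P']:.2f} cm "
    f"(truth {config.l_p})"
)

biological = fit_bioirrigation(refaunated, physical, fit_config, seed=0)
print(
    f"bioirrigation:      a_B = {biological.parameters['a_B']:.3f}/d "
    f"(truth {config.a_b}), window {biological.parameters['z1']:.1f}-"
    f"{biological.parameters['z2']:.1f} cm (truth {config.z1}-{config.z2})"
)
print(
    "The defaunated fit absorbs wave/tide pumping; the refaunated increment\n"
    "is the porewater exchange attributable to lugworm burrow flushing."
)
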