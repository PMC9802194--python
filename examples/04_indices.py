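"""Geochemical and gene-abundance indices with zone comparisons.

Computes the pigment freshness index, three-domain rRNA gene ratios,
functional-gene fractions of total 16S, assigns sediment zones, and
compares the biologically impacted layer (BL) between treatments with
Welch's t test.
"""

import numpy as np

from bioturb import (
    CommunityScenario,
    ScenarioConfig,
    assign_zone,
    domain_ratios,
    freshness_index,
    functional_fractions,
    generate_community,
    welch_t,
)

run = generate_community(CommunityScenario(), ScenarioConfig(), seed=3)
profile = run["gene_profiles"]["bioturbated"]

ratios = domain_ratios(profile)
fractions = functional_fractions(profile)
for depth in (1.0, 18.0, 35.0):
    i = int(np.argmin(np.abs(profile.depth - depth)))
    zone = assign_zone(profile.depth[i], "bioturbated").value
    print(
        f"{profile.depth[i]:5.1f} cm [{zone:>3}]: BAR = {ratios['BAR'][i]:7.1f}, "
        f"EBR = {ratios['EBR'][i]:.4f}, dsrB = {fractions['dsrB_pct'][i]:.2f}% of 16S"
    )

print(f"freshness_index(chl=2, pheo=2) = {freshness_index(2.0, 2.0):.2f}")

gp_non = run["gene_profiles"]["nonbioturbated"]
bl_bio = (profile.depth >= 12.5) & (profile.depth < 25)
bl_non = (gp_non.depth >= 12.5) & (gp_non.depth < 25)
res = welch_t(
    np.log10(profile.copies["bac16S"].to_numpy()[bl_bio]),
    np.log10(gp_non.copies["bac16S"].to_numpy()[bl_non]),
)
print(
    f"BL bacterial 16S, bioturbated vs control: t = {res.statistic:.2f}, "
    f"df = {res.df:.1f}, p = {res.p_value:.2e}"
)
print(
    "The planted ~2-order BL depletion of prokaryotic gene copies in the\n"
    "bioturbated arm is picked up as a strongly significant Welch test."
)
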