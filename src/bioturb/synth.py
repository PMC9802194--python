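"""Synthetic-data generator for every input the pipeline consumes.

The generator emulates the statistical structure of a two-treatment
intertidal mesocosm/field study: defaunated (physical mixing only) vs
refaunated/bioturbated (physical mixing plus lugworm activity), depths
0-40 cm, time points T1-T4, with

* porewater DIC and sulfate profiles produced by the nonlocal-exchange
  forward model plus multiplicative log-normal noise;
* steady pigment profiles and sand-fraction profiles carrying a planted
  feeding signal (coarse-sand enrichment over the worm's feeding window);
* qPCR gene-copy profiles with a planted depletion in the biologically
  impacted layer (12.5-25 cm) of the bioturbated arm, ~2 orders of
  magnitude for prokaryotes and ~1 for eukaryotes;
* depth-structured ZOTU tables per domain with "surface" and
  "subsurface" lineage pools (opposite logistic depth responses) and
  planted correlation clusters driven by shared log-normal latent
  factors, plus a random coalescent-style tree.

Every generator is a pure function of (config, seed): identical inputs
give bit-identical outputs.  Truth sidecars carry the planted parameters
for recovery scoring.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from .grid import Grid1D, build_grid
from .indices import GeneAbundanceProfile, assign_zone
from .inversion import PigmentModelConfig, PorewaterModelConfig, ProfileObservation
from .transport import (
    ExchangeField,
    SoluteState,
    TransportParameters,
    exponential_profile,
    solve_solute,
    steady_state_pigments,
    window_profile,
)

__all__ = [
    "ScenarioConfig",
    "CommunityScenario",
    "generate_geochem",
    "generate_pigments_grainsize",
    "generate_community",
    "random_coalescent_tree",
]


@dataclass
class ScenarioConfig:
    """The stated world: true parameters and observation design.

    Mixing parameters follow the amplitude-x-window forms of the forward
    models; values are chosen as field-realistic for a wave-worked
    intertidal sand with Abarenicola at natural density (porewater
    exchange a fraction of 1/day, burrow irrigation over ~8-18 cm,
    particle biodiffusion ~0.5 cm^2/day over the feeding depths).
    """

    # true porewater mixing
    a_p: float = 0.3  # 1/day, physical exchange amplitude
    l_p: float = 4.0  # cm, physical e-folding depth
    a_b: float = 0.15  # 1/day, bioirrigation amplitude
    z1: float = 8.0  # cm, bioirrigation window top
    z2: float = 18.0  # cm, bioirrigation window bottom
    # true particle mixing
    d_p: float = 2.0  # cm^2/day, physical biodiffusion amplitude
    l_dp: float = 4.0  # cm
    d_b: float = 0.5  # cm^2/day, biological biodiffusion
    d_b_window: tuple[float, float] = (5.0, 20.0)
    # pigment tracer
    k_chl: float = 0.05  # 1/day
    k_pheo: float = 0.005  # 1/day
    chl_to_pheo_yield: float = 1.0
    surface_chl_flux: float = 1.0  # ug cm^-2 day^-1
    # column and solutes
    depth_max: float = 40.0
    n_cells: int = 80
    porosity: float = 0.4
    diffusivity: Mapping[str, float] = field(
        default_factory=lambda: {"DIC": 1.0, "SO4": 0.48}
    )
    overlying_conc: Mapping[str, float] = field(
        default_factory=lambda: {"DIC": 2.2, "SO4": 28.0}
    )
    production: Mapping[str, float] = field(
        default_factory=lambda: {"DIC": 0.25, "SO4": -0.125}
    )
    # observation design (T1/T2 drive the calibration, replicates I-III)
    obs_depths: tuple = tuple(np.arange(1.0, 30.0, 2.0))  # 15 depths
    time_points: Mapping[str, float] = field(
        default_factory=lambda: {"T1": 14.0, "T2": 28.0}
    )
    replicates: tuple = ("I", "II", "III")
    noise_sigma: Mapping[str, float] = field(
        default_factory=lambda: {
            "DIC": 0.05,
            "SO4": 0.05,
            "chl_a": 0.05,
            "pheopigment": 0.05,
        }
    )
    dt_days: float = 0.5  # solver step shared by generator and calibration
    # grain size / feeding
    sand_base: float = 0.72
    sand_noise: float = 0.02  # additive Gaussian, clipped to [0, 1]
    feeding_bump: float = 0.2
    feeding_window: tuple[float, float] = (15.0, 25.0)
    seed: int = 0

    def grid(self) -> Grid1D:
        return build_grid(self.depth_max, self.n_cells, self.porosity)

    def exchange_field(self, grid: Grid1D, biological: bool) -> ExchangeField:
        alpha_p = exponential_profile(grid, self.a_p, self.l_p)
        if biological:
            alpha_b = window_profile(grid, self.a_b, self.z1, self.z2, 1.0)
        else:
            alpha_b = np.zeros(grid.n_cells)
        return ExchangeField(alpha_physical=alpha_p, alpha_biological=alpha_b)

    def porewater_config(self, grid: Grid1D | None = None) -> PorewaterModelConfig:
        return PorewaterModelConfig(
            grid=grid or self.grid(),
            diffusivity=dict(self.diffusivity),
            overlying_conc=dict(self.overlying_conc),
            production=dict(self.production),
            dt=self.dt_days,
        )

    def pigment_config(self, grid: Grid1D | None = None) -> PigmentModelConfig:
        return PigmentModelConfig(
            grid=grid or self.grid(),
            chl_decay=self.k_chl,
            pheo_decay=self.k_pheo,
            chl_to_pheo_yield=self.chl_to_pheo_yield,
            surface_chl_flux=self.surface_chl_flux,
            biological_window=self.d_b_window,
        )


def _lognormal_noise(rng: np.random.Generator, values: np.ndarray, sigma: float):
    if sigma == 0:
        return values.copy()
    return values * np.exp(rng.normal(0.0, sigma, size=values.shape))


def generate_geochem(config: ScenarioConfig, seed: int | None = None) -> dict:
    """Porewater DIC and sulfate observations for both treatments.

    Runs the forward model from homogenized initial conditions (uniform
    at the overlying-water value, as after sieving) with physical
    exchange only (defaunated) and physical + biological exchange
    (refaunated), samples at the configured depths/times, and applies
    seeded log-normal noise.  Returns ``{"observations": [...],
    "truth": {...}}``; truth carries noiseless profiles and parameters.
    """
    if not 0 < config.porosity < 1:
        raise ValueError("porosity must be in (0, 1)")
    master = config.seed if seed is None else seed
    grid = config.grid()
    days = sorted(config.time_points.values())
    day_of = {v: k for k, v in config.time_points.items()}
    # noise streams keyed by (analyte, time point, replicate) but NOT by
    # treatment: with a_B = 0 the two treatments are bit-identical.
    def _noise_rng(analyte: str, tp: str, rep: str) -> np.random.Generator:
        key = [ord(ch) for ch in f"{analyte}|{tp}|{rep}"]
        return np.random.default_rng(np.random.SeedSequence([master, 7, *key]))

    observations: list[ProfileObservation] = []
    truth_profiles = {}
    for treatment, biological in (("defaunated", False), ("refaunated", True)):
        exchange = config.exchange_field(grid, biological)
        for analyte in sorted(config.diffusivity):
            params = TransportParameters(
                molecular_diffusivity=config.diffusivity[analyte],
                production=config.production.get(analyte, 0.0),
            )
            c_ow = config.overlying_conc[analyte]
            initial = SoluteState(analyte, np.full(grid.n_cells, c_ow), c_ow)
            states = solve_solute(
                grid, params, exchange, initial, max(days), days, dt=config.dt_days
            )
            for s in states:
                clean = np.interp(np.asarray(config.obs_depths), grid.cell_centers, s.concentration)
                truth_profiles[(treatment, analyte, day_of[s.time])] = clean
                for rep in config.replicates:
                    rng = _noise_rng(analyte, day_of[s.time], rep)
                    noisy = _lognormal_noise(rng, clean, config.noise_sigma.get(analyte, 0.0))
                    observations.append(
                        ProfileObservation(
                            analyte=analyte,
                            treatment=treatment,
                            time_point=day_of[s.time],
                            days=s.time,
                            depths=np.asarray(config.obs_depths),
                            values=noisy,
                            replicate=rep,
                        )
                    )
    truth = {
        "a_P": config.a_p, "L_P": config.l_p,
        "a_B": config.a_b, "z1": config.z1, "z2": config.z2,
        "profiles": truth_profiles,
    }
    return {"observations": observations, "truth": truth}


def generate_pigments_grainsize(config: ScenarioConfig, seed: int | None = None) -> dict:
    """Steady pigment profiles plus sand-fraction profiles per treatment.

    Pigments come from the solid-tracer steady state (D_P only for the
    nonbioturbated column, D_P + D_B for the bioturbated one).  Sand
    fraction is constant + noise for the control and gains a positive
    bump over the feeding window in the bioturbated column, so that the
    feeding-intensity proxy recovers the planted window.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    grid = config.grid()
    observations: list[ProfileObservation] = []
    truth_profiles = {}
    depths = np.asarray(config.obs_depths)
    for treatment, biological in (("nonbioturbated", False), ("bioturbated", True)):
        d_b = config.d_b if biological else 0.0
        params = TransportParameters(
            biodiffusion_physical=exponential_profile(grid, config.d_p, config.l_dp),
            biodiffusion_biological=window_profile(grid, d_b, *config.d_b_window, 1.0),
            chl_decay=config.k_chl,
            pheo_decay=config.k_pheo,
            chl_to_pheo_yield=config.chl_to_pheo_yield,
            surface_chl_flux=config.surface_chl_flux,
        )
        state = steady_state_pigments(grid, params)
        for analyte, profile in (("chl_a", state.chl_a), ("pheopigment", state.pheopigment)):
            clean = np.interp(depths, grid.cell_centers, profile)
            truth_profiles[(treatment, analyte)] = clean
            noisy = _lognormal_noise(rng, clean, config.noise_sigma.get(analyte, 0.0))
            observations.append(
                ProfileObservation(
                    analyte=analyte, treatment=treatment, time_point="steady",
                    days=0.0, depths=depths, values=noisy,
                )
            )
    # sand fractions on a finer support
    sand_depths = np.arange(0.5, config.depth_max, 1.0)
    bump = np.zeros_like(sand_depths)
    z1, z2 = config.feeding_window
    core = (sand_depths >= z1) & (sand_depths <= z2)
    bump[core] = config.feeding_bump
    edge = 2.0
    up = (sand_depths >= z1 - edge) & (sand_depths < z1)
    bump[up] = config.feeding_bump * 0.5 * (1 + np.cos(np.pi * (z1 - sand_depths[up]) / edge))
    dn = (sand_depths > z2) & (sand_depths <= z2 + edge)
    bump[dn] = config.feeding_bump * 0.5 * (1 + np.cos(np.pi * (sand_depths[dn] - z2) / edge))
    sand_control = np.clip(
        config.sand_base + rng.normal(0, config.sand_noise, sand_depths.shape), 0, 1
    )
    sand_bioturbated = np.clip(
        config.sand_base + bump + rng.normal(0, config.sand_noise, sand_depths.shape), 0, 1
    )
    truth = {
        "d_P": config.d_p, "L_DP": config.l_dp, "d_B": config.d_b,
        "window": config.d_b_window,
        "feeding_bump": config.feeding_bump,
        "feeding_window": config.feeding_window,
        "profiles": truth_profiles,
    }
    return {
        "observations": observations,
        "sand_depths": sand_depths,
        "sand_bioturbated": sand_bioturbated,
        "sand_control": sand_control,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# community generator


@dataclass
class CommunityScenario:
    """Planted community structure for the three marker-gene datasets.

    Each domain holds classes tagged surface / subsurface / neutral.
    Surface classes decrease logistically with depth, subsurface classes
    mirror them; the surface and subsurface pools each share a latent
    log-normal factor (the planted correlation clusters), and those
    factors are shared across domains so interdomain dependence is
    planted too.  The biologically impacted layer (BL, 12.5-25 cm) of
    the bioturbated arm carries a fold-depletion of qPCR totals and a
    detection-driven richness loss (BL-sensitive ZOTUs are suppressed).
    """

    domains: tuple = ("bac16S", "arc16S", "euk18S")
    n_classes_per_role: int = 4  # surface, subsurface, neutral each
    n_zotus_per_class: int = 6
    depth_midpoint: float = 10.0  # cm, logistic response midpoint
    depth_steepness: float = 4.0  # cm
    depth_effect: float = 2.0  # natural-log span of the logistic response
    cluster_sigma: float = 1.0  # SD of the shared latent factor
    noise_sigma: float = 0.4  # per-class independent log noise
    zotu_noise_sigma: float = 0.2  # per-ZOTU log noise
    # BL (12.5-25 cm) effects in the bioturbated arm
    qpcr_bl_depletion: Mapping[str, float] = field(
        default_factory=lambda: {"bac16S": 100.0, "arc16S": 100.0, "euk18S": 10.0}
    )
    bl_sensitive_fraction: float = 0.5
    bl_sensitive_suppression: float = 0.02  # abundance multiplier in the BL
    # sampling design
    sample_depths: tuple = (1.0, 3.0, 6.0, 9.0, 14.0, 18.0, 22.0, 28.0, 35.0)
    time_points: tuple = ("T1", "T2")
    seq_depth_range: tuple[int, int] = (15000, 25000)
    # qPCR depth trend: log10 copies at surface and at depth_max
    qpcr_surface_log10: Mapping[str, float] = field(
        default_factory=lambda: {"bac16S": 9.3, "arc16S": 8.0, "euk18S": 7.5}
    )
    qpcr_bottom_log10: Mapping[str, float] = field(
        default_factory=lambda: {"bac16S": 8.3, "arc16S": 7.5, "euk18S": 5.5}
    )
    qpcr_noise_sigma: float = 0.15  # log10 units
    functional_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"dsrB": 0.03, "soxB": 0.008, "narG": 0.006, "amoA": 0.002}
    )

    def validate(self) -> None:
        if self.n_classes_per_role < 1 or self.n_zotus_per_class < 1:
            raise ValueError("lineage pools must be non-empty")
        if any(f < 1 for f in self.qpcr_bl_depletion.values()):
            raise ValueError("fold-depletions must be >= 1")


def random_coalescent_tree(taxon_ids, rng: np.random.Generator) -> TreeNode:
    """Random binary topology with exponential branch lengths.

    A valid rooted tree for UniFrac; no attempt to mimic real phylogeny.
    """
    nodes = [f"{t}:{rng.exponential(0.1):.6f}" for t in taxon_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(0.1):.6f}")
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    return TreeNode.read(io.StringIO(newick), convert_underscores=False)


def _logistic(depth, midpoint, steepness):
    return 1.0 / (1.0 + np.exp((depth - midpoint) / steepness))


def generate_community(
    scenario: CommunityScenario, config: ScenarioConfig, seed: int | None = None
) -> dict:
    """ZOTU tables, trees and qPCR profiles with planted structure.

    Returns a dict with ``tables`` (domain -> ZOTUTable), ``trees``
    (domain -> TreeNode), ``gene_profiles`` (treatment ->
    GeneAbundanceProfile) and ``truth`` (planted cluster membership,
    depletion factors, sensitive-taxon lists).
    """
    scenario.validate()
    master = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([master, 2]))

    roles = ("surface", "subsurface", "neutral")
    samples = []
    for treatment in ("bioturbated", "nonbioturbated"):
        for tp in scenario.time_points:
            for depth in scenario.sample_depths:
                sid = f"{treatment[:3]}_{tp}_{depth:g}cm"
                samples.append(
                    {
                        "sample_id": sid,
                        "treatment": treatment,
                        "time_point": tp,
                        "depth": depth,
                        "zone": assign_zone(depth, treatment).value,
                    }
                )
    meta = pd.DataFrame(samples).set_index("sample_id")
    n_samples = len(meta)
    depths_arr = meta["depth"].to_numpy()
    in_bl = (
        (meta["treatment"] == "bioturbated")
        & (depths_arr >= 12.5)
        & (depths_arr < 25.0)
    ).to_numpy()

    # latent cluster factors, shared across domains (per sample)
    factors = {
        role: rng.normal(0.0, scenario.cluster_sigma, n_samples)
        for role in ("surface", "subsurface")
    }

    tables: dict[str, "ZOTUTable"] = {}
    trees: dict[str, TreeNode] = {}
    truth_clusters: dict[str, pd.Series] = {}
    sensitive: dict[str, list[str]] = {}
    from .ecology import ZOTUTable  # deferred: avoids import cycle at module load

    for domain in scenario.domains:
        class_names, class_role = [], {}
        for role in roles:
            for i in range(scenario.n_classes_per_role):
                name = f"{domain}_{role[:4]}{i + 1}"
                class_names.append(name)
                class_role[name] = role
        taxa, taxonomy_rows = [], []
        zotu_class = {}
        for cname in class_names:
            for z in range(scenario.n_zotus_per_class):
                zid = f"{cname}_z{z + 1}"
                taxa.append(zid)
                zotu_class[zid] = cname
                taxonomy_rows.append(
                    {
                        "zotu": zid,
                        "domain": domain,
                        "phylum": f"{cname}_phylum",
                        "class": cname,
                        "order": "unclassified",
                        "family": "unclassified",
                        "genus": "unclassified",
                    }
                )
        taxonomy = pd.DataFrame(taxonomy_rows).set_index("zotu")
        # per-ZOTU base weights within a class (drawn once per scenario)
        zotu_w = {
            zid: w
            for cname in class_names
            for zid, w in zip(
                [f"{cname}_z{z + 1}" for z in range(scenario.n_zotus_per_class)],
                rng.dirichlet(np.full(scenario.n_zotus_per_class, 2.0)),
            )
        }
        n_sens = int(round(scenario.bl_sensitive_fraction * len(taxa)))
        sens = list(rng.choice(taxa, size=n_sens, replace=False))
        sensitive[domain] = sens
        sens_set = set(sens)

        # latent log abundance per class per sample
        log_abund = np.zeros((n_samples, len(taxa)))
        col = 0
        for cname in class_names:
            role = class_role[cname]
            resp = _logistic(depths_arr, scenario.depth_midpoint, scenario.depth_steepness)
            if role == "surface":
                mu = scenario.depth_effect * resp
                f = factors["surface"]
            elif role == "subsurface":
                mu = scenario.depth_effect * (1.0 - resp)
                f = factors["subsurface"]
            else:
                mu = np.full(n_samples, 0.5 * scenario.depth_effect)
                f = rng.normal(0.0, scenario.cluster_sigma, n_samples)
            eps = rng.normal(0.0, scenario.noise_sigma, n_samples)
            class_log = mu + f + eps
            for z in range(scenario.n_zotus_per_class):
                zid = f"{cname}_z{z + 1}"
                zeps = rng.normal(0.0, scenario.zotu_noise_sigma, n_samples)
                log_abund[:, col] = class_log + np.log(zotu_w[zid]) + zeps
                if zid in sens_set and scenario.bl_sensitive_suppression < 1.0:
                    log_abund[in_bl, col] += np.log(scenario.bl_sensitive_suppression)
                col += 1
        rel = np.exp(log_abund)
        rel /= rel.sum(axis=1, keepdims=True)
        counts = np.zeros_like(rel, dtype=np.int64)
        for i in range(n_samples):
            depth_reads = int(rng.integers(*scenario.seq_depth_range))
            counts[i] = rng.multinomial(depth_reads, rel[i])
        # guard the every-sample-positive invariant (astronomically unlikely to trip)
        empty = counts.sum(axis=1) == 0
        counts[empty, 0] = 1
        tables[domain] = ZOTUTable(
            counts=pd.DataFrame(counts, index=meta.index, columns=taxa),
            taxonomy=taxonomy,
            sample_metadata=meta,
            domain=domain,
        )
        trees[domain] = random_coalescent_tree(taxa, rng)
        truth_clusters[domain] = pd.Series(class_role)

    gene_profiles = _qpcr_profiles(scenario, meta, rng)
    return {
        "tables": tables,
        "trees": trees,
        "gene_profiles": gene_profiles,
        "metadata": meta,
        "truth": {
            "clusters": truth_clusters,
            "qpcr_bl_depletion": dict(scenario.qpcr_bl_depletion),
            "bl_sensitive": sensitive,
            "seed": master,
        },
    }


def _qpcr_profiles(scenario: CommunityScenario, meta: pd.DataFrame, rng) -> dict:
    """qPCR profiles per treatment with the planted BL depletion."""
    from .indices import GENE_COLUMNS

    profiles = {}
    depth_max = max(scenario.sample_depths)
    for treatment in ("bioturbated", "nonbioturbated"):
        sub = meta[meta["treatment"] == treatment]
        depths = np.asarray(sorted(sub["depth"].unique()))
        in_bl = (treatment == "bioturbated") & (depths >= 12.5) & (depths < 25.0)
        cols = {}
        for marker in ("bac16S", "arc16S", "euk18S"):
            top = scenario.qpcr_surface_log10[marker]
            bot = scenario.qpcr_bottom_log10[marker]
            log10 = top + (bot - top) * depths / depth_max
            log10 = log10 - np.where(in_bl, np.log10(scenario.qpcr_bl_depletion[marker]), 0.0)
            log10 = log10 + rng.normal(0.0, scenario.qpcr_noise_sigma, depths.shape)
            cols[marker] = 10.0**log10
        total16s = cols["bac16S"] + cols["arc16S"]
        for gene, frac in scenario.functional_fraction.items():
            noise = rng.normal(0.0, scenario.qpcr_noise_sigma, depths.shape)
            cols[gene] = frac * total16s * 10.0**noise
        # rbcL markers: photosynthetic material, surface-concentrated
        for gene, top_l in (("rbcL_ochrophyta", 7.0), ("rbcL_vascular", 5.0)):
            log10 = top_l - 2.5 * depths / depth_max
            log10 = log10 + rng.normal(0.0, scenario.qpcr_noise_sigma, depths.shape)
            cols[gene] = 10.0**log10
        copies = pd.DataFrame({g: cols[g] for g in GENE_COLUMNS})
        profiles[treatment] = GeneAbundanceProfile(
            depth=depths, copies=copies, treatment=treatment, time_point="T1"
        )
    return profiles
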