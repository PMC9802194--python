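"""Simulation-study harnesses: parameter recovery under stated noise.

Each study repeats generate -> fit -> score over seeded replicates and
reports per-parameter recovery fractions and bias, the package's
built-in answer to "how well can these mixing parameters be estimated
from profiles like ours?".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .inversion import fit_bioirrigation, fit_particle_mixing, fit_physical_porewater
from .synth import ScenarioConfig, generate_geochem, generate_pigments_grainsize

__all__ = ["RecoveryStudy", "porewater_recovery_study", "pigment_recovery_study"]


@dataclass
class RecoveryStudy:
    """Replicate-level estimates and recovery summaries for one study."""

    parameter_truth: dict[str, float]
    estimates: dict[str, np.ndarray]
    tolerance: dict[str, float]

    def within_tolerance(self, name: str) -> float:
        """Fraction of replicates with |estimate/truth - 1| <= tolerance."""
        est = self.estimates[name]
        truth = self.parameter_truth[name]
        return float(np.mean(np.abs(est / truth - 1.0) <= self.tolerance[name]))

    def bias(self, name: str) -> float:
        return float(np.mean(self.estimates[name]) / self.parameter_truth[name] - 1.0)


def porewater_recovery_study(
    config: ScenarioConfig | None = None,
    n_replicates: int = 50,
    seed: int = 0,
    fit_n_cells: int = 32,
    xtol: float = 1e-4,
    tolerance: float = 0.20,
) -> RecoveryStudy:
    """Recovery of a_P and a_B from noisy synthetic DIC/sulfate profiles.

    Each replicate draws fresh observation noise, runs the two-stage
    porewater calibration (physical on defaunated, bioirrigation on
    refaunated) and records the estimates.  The fit uses a coarser grid
    and a looser optimizer tolerance than the defaults: estimation noise
    under 5% observation error dwarfs both, and 50 replicates have to
    stay cheap.  The coarser grid also means this is not a pure inverse
    crime in the discretization.
    """
    config = config or ScenarioConfig()
    a_p_est, a_b_est = [], []
    fit_cfg = replace(
        config.porewater_config(
            grid=None if fit_n_cells is None else _coarse_grid(config, fit_n_cells)
        ),
        xtol=xtol,
    )
    for r in range(n_replicates):
        rep_seed = seed * 100003 + r
        data = generate_geochem(config, seed=rep_seed)
        defaunated = [o for o in data["observations"] if o.treatment == "defaunated"]
        refaunated = [o for o in data["observations"] if o.treatment == "refaunated"]
        phys = fit_physical_porewater(defaunated, fit_cfg, seed=rep_seed)
        bio = fit_bioirrigation(refaunated, phys, fit_cfg, seed=rep_seed)
        a_p_est.append(phys.parameters["a_P"])
        a_b_est.append(bio.parameters["a_B"])
    return RecoveryStudy(
        parameter_truth={"a_P": config.a_p, "a_B": config.a_b},
        estimates={"a_P": np.asarray(a_p_est), "a_B": np.asarray(a_b_est)},
        tolerance={"a_P": tolerance, "a_B": tolerance},
    )


def pigment_recovery_study(
    config: ScenarioConfig | None = None,
    n_replicates: int = 50,
    seed: int = 0,
    fit_n_cells: int = 80,
    xtol: float = 1e-4,
    tolerance: float = 0.25,
) -> RecoveryStudy:
    """Recovery of d_B from noisy steady pigment profiles.

    The fit grid matches the generator's 0.5 cm resolution: the log-scale
    pigment loss weights the deep exponential tail, where a coarser
    grid's discretization error would bias d_B low.
    """
    config = config or ScenarioConfig()
    fit_cfg = replace(
        config.pigment_config(
            grid=None if fit_n_cells is None else _coarse_grid(config, fit_n_cells)
        ),
        xtol=xtol,
    )
    d_b_est, d_p_est = [], []
    for r in range(n_replicates):
        rep_seed = seed * 100003 + r
        data = generate_pigments_grainsize(config, seed=rep_seed)
        fit = fit_particle_mixing(data["observations"], fit_cfg, seed=rep_seed)
        d_b_est.append(fit.parameters["d_B"])
        d_p_est.append(fit.parameters["d_P"])
    return RecoveryStudy(
        parameter_truth={"d_B": config.d_b, "d_P": config.d_p},
        estimates={"d_B": np.asarray(d_b_est), "d_P": np.asarray(d_p_est)},
        tolerance={"d_B": tolerance, "d_P": tolerance},
    )


def _coarse_grid(config: ScenarioConfig, n_cells: int):
    from .grid import build_grid

    return build_grid(config.depth_max, n_cells, config.porosity)
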