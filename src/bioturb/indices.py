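"""Per-depth geochemical and gene-abundance indices.

Scalar summaries derived from raw profiles: the pigment freshness index,
three-domain rRNA gene ratios, functional-gene fractions relative to total
16S copies, sediment-zone assignment, and Welch's unequal-variance t test
used for between-zone comparisons.

Naming caveat: the source data display labels the domain ratios
Bacteria-to-Archaea (BAR), Archaea-to-Eukarya and Bacteria-to-Eukarya,
while the accompanying text defines Eukarya:Archaea (EAR) and
Eukarya:Bacteria (EBR) ratios that fall from ~10^1 to ~10^-2 with depth.
We follow the text: Eukarya in the numerator for EAR and EBR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneAbundanceProfile",
    "Zone",
    "freshness_index",
    "domain_ratios",
    "functional_fractions",
    "assign_zone",
    "welch_t",
    "WelchResult",
]

GENE_COLUMNS = (
    "bac16S",
    "arc16S",
    "euk18S",
    "dsrB",
    "soxB",
    "narG",
    "amoA",
    "rbcL_ochrophyta",
    "rbcL_vascular",
)

FUNCTIONAL_GENES = ("dsrB", "soxB", "narG", "amoA")


@dataclass
class GeneAbundanceProfile:
    """qPCR gene-copy profiles (copies per g wet sediment) vs depth."""

    depth: np.ndarray
    copies: pd.DataFrame  # columns from GENE_COLUMNS
    treatment: str = ""
    time_point: str = ""

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        missing = [c for c in self.copies.columns if c not in GENE_COLUMNS]
        if missing:
            raise ValueError(f"unknown gene columns: {missing}")
        vals = self.copies.to_numpy(dtype=float)
        if len(self.depth) != len(self.copies):
            raise ValueError("depth and copies must have equal length")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("gene copy numbers must be finite and >= 0")


class Zone(str, Enum):
    """Sediment zones of the bioturbated / nonbioturbated columns.

    PBL: physically and biologically impacted layer (0-12.5 cm,
    bioturbated); BL: biologically impacted layer (12.5-25 cm,
    bioturbated); UL: undisturbed layer below; PL: physically impacted
    layer (0-12.5 cm, nonbioturbated).
    """

    PBL = "PBL"
    BL = "BL"
    UL = "UL"
    PL = "PL"


def freshness_index(chl_a, pheopigment):
    """Pigment freshness: chl a / (chl a + pheopigments), in [0, 1].

    1 means undegraded algal pigment, 0 fully degraded.  Where both
    pigments are zero the index is undefined and returned as NaN.
    Element-wise over arrays; scale-invariant.
    """
    chl = np.asarray(chl_a, dtype=float)
    pheo = np.asarray(pheopigment, dtype=float)
    if np.any(chl < 0) or np.any(pheo < 0):
        raise ValueError("pigment concentrations must be >= 0")
    total = chl + pheo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, chl / np.where(total > 0, total, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def domain_ratios(profile: GeneAbundanceProfile) -> pd.DataFrame:
    """Three-domain rRNA gene ratios per depth: BAR, EAR, EBR.

    BAR = bac16S / arc16S; EAR = euk18S / arc16S; EBR = euk18S / bac16S.
    Ratios are computed on linear copy numbers (display may log them).
    A zero denominator yields NaN at that depth for that ratio only.
    """
    bac = profile.copies["bac16S"].to_numpy(float)
    arc = profile.copies["arc16S"].to_numpy(float)
    euk = profile.copies["euk18S"].to_numpy(float)

    def _ratio(num, den):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

    return pd.DataFrame(
        {
            "depth_cm": profile.depth,
            "BAR": _ratio(bac, arc),
            "EAR": _ratio(euk, arc),
            "EBR": _ratio(euk, bac),
        }
    )


def functional_fractions(profile: GeneAbundanceProfile) -> pd.DataFrame:
    """Functional-gene percentages of total 16S copies per depth.

    100 * gene / (bac16S + arc16S) for dsrB, soxB, narG and amoA.  A zero
    16S total yields NaN; fractions above 100% are kept but flagged in the
    ``out_of_range`` column (copies of a single-copy marker exceeding
    total 16S is biologically implausible).
    """
    total16s = (
        profile.copies["bac16S"].to_numpy(float) + profile.copies["arc16S"].to_numpy(float)
    )
    out = {"depth_cm": profile.depth}
    flag = np.zeros(len(profile.depth), dtype=bool)
    for gene in FUNCTIONAL_GENES:
        g = profile.copies[gene].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(total16s > 0, 100.0 * g / np.where(total16s > 0, total16s, 1.0), np.nan)
        flag |= np.nan_to_num(frac) >= 100.0 - 1e-9
        out[f"{gene}_pct"] = frac
    df = pd.DataFrame(out)
    df["out_of_range"] = flag
    return df


_BIOTURBATED = {"bioturbated", "refaunated"}
_NONBIOTURBATED = {"nonbioturbated", "non-bioturbated", "defaunated", "control"}


def assign_zone(depth: float, treatment: str) -> Zone:
    """Zone label for a depth (cm) under a treatment.

    Bioturbated columns: PBL on [0, 12.5), BL on [12.5, 25), UL at and
    below 25 cm.  Nonbioturbated: PL on [0, 12.5), UL at and below
    12.5 cm.  Boundaries are half-open, lower-inclusive of the deeper
    zone.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    t = treatment.lower()
    if t in _BIOTURBATED:
        if depth < 12.5:
            return Zone.PBL
        if depth < 25.0:
            return Zone.BL
        return Zone.UL
    if t in _NONBIOTURBATED:
        return Zone.PL if depth < 12.5 else Zone.UL
    raise ValueError(f"unknown treatment: {treatment!r}")


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    df: float
    p_value: float


def welch_t(group_a, group_b) -> WelchResult:
    """Welch's unequal-variance two-sample t test, two-sided.

    Returns the t statistic, Welch-Satterthwaite fractional degrees of
    freedom, and the two-sided p-value.  Two exactly identical groups
    (zero pooled variance, zero difference) return t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    delta = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        # exact-equality fast path: no variance to scale against
        if delta == 0.0:
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0)
        return WelchResult(math.copysign(math.inf, delta), float(len(a) + len(b) - 2), 0.0)
    sa, sb = va / len(a), vb / len(b)
    t = delta / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))
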