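"""Readers and writers for the pipeline's plain-text formats.

Profile tables are TSV with columns depth_cm, value, analyte, units,
treatment, time_point, replicate (one header line, UTF-8).  ZOTU tables
use the classic taxa x samples TSV dialect with a trailing taxonomy
column; metadata is TSV keyed by sample identifier; trees are Newick.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .ecology import TAXONOMY_RANKS, ZOTUTable
from .inversion import ProfileObservation

PROFILE_COLUMNS = ["depth_cm", "value", "analyte", "units", "treatment", "time_point", "replicate"]


def write_profiles(
    observations: Sequence[ProfileObservation],
    path,
    units: dict[str, str] | None = None,
    days: dict[str, float] | None = None,
) -> None:
    """Write observations to the profile TSV dialect."""
    units = units or {}
    rows = []
    for o in observations:
        for d, v in zip(o.depths, o.values):
            rows.append(
                {
                    "depth_cm": d,
                    "value": v,
                    "analyte": o.analyte,
                    "units": units.get(o.analyte, ""),
                    "treatment": o.treatment,
                    "time_point": o.time_point,
                    "replicate": o.replicate,
                    "days": o.days,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> list[ProfileObservation]:
    """Read a profile TSV back into ProfileObservation objects."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PROFILE_COLUMNS) - {"units"} - set(df.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    out = []
    keys = ["analyte", "treatment", "time_point", "replicate"]
    for vals, sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("depth_cm")
        days = float(sub["days"].iloc[0]) if "days" in sub.columns else 0.0
        out.append(
            ProfileObservation(
                analyte=vals[0],
                treatment=vals[1],
                time_point=str(vals[2]),
                days=days,
                depths=sub["depth_cm"].to_numpy(float),
                values=sub["value"].to_numpy(float),
                replicate=str(vals[3]),
            )
        )
    return out


def write_zotu_table(table: ZOTUTable, counts_path, metadata_path=None) -> None:
    """Classic QIIME-style TSV: taxa rows, sample columns, taxonomy last."""
    df = table.counts.T.copy()
    df.index.name = "#ZOTU ID"
    lineage = table.taxonomy.loc[df.index, [r for r in TAXONOMY_RANKS if r in table.taxonomy.columns]]
    df["taxonomy"] = lineage.apply(lambda row: "; ".join(str(v) for v in row), axis=1)
    df.to_csv(counts_path, sep="\t")
    if metadata_path is not None:
        meta = table.sample_metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")


def read_zotu_table(counts_path, metadata_path, domain: str = "") -> ZOTUTable:
    """Read the classic taxa x samples TSV (taxonomy column) + metadata TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if "taxonomy" not in df.columns:
        raise ValueError("ZOTU table needs a taxonomy column")
    lineage = df.pop("taxonomy").str.split(";\\s*", regex=True, expand=True)
    lineage.columns = list(TAXONOMY_RANKS[: lineage.shape[1]])
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    counts = df.T
    counts.index = counts.index.astype(str)
    return ZOTUTable(
        counts=counts.astype(np.int64),
        taxonomy=lineage,
        sample_metadata=meta.loc[counts.index],
        domain=domain,
    )


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick", convert_underscores=False)
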