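import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from bioturb import ScenarioConfig, ZOTUTable, build_grid


@pytest.fixture
def grid():
    return build_grid(40.0, 80, 0.4)


@pytest.fixture
def fine_grid():
    return build_grid(40.0, 160, 0.4)


@pytest.fixture
def noiseless_config():
    return ScenarioConfig(
        noise_sigma={"DIC": 0.0, "SO4": 0.0, "chl_a": 0.0, "pheopigment": 0.0},
        sand_noise=0.0,
    )


def make_table(counts, sample_ids=None, classes=None, domain="bac16S", depths=None,
               treatments=None):
    """Small ZOTUTable from a raw count array."""
    counts = np.asarray(counts)
    n, m = counts.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    taxa = [f"t{j}" for j in range(m)]
    classes = classes or [f"c{j % 3}" for j in range(m)]
    taxonomy = pd.DataFrame(
        {
            "domain": ["Bacteria"] * m,
            "phylum": [f"p{j % 2}" for j in range(m)],
            "class": classes,
            "order": ["unclassified"] * m,
            "family": ["unclassified"] * m,
            "genus": ["unclassified"] * m,
        },
        index=taxa,
    )
    meta = pd.DataFrame(
        {
            "depth": depths if depths is not None else np.linspace(1, 30, n),
            "treatment": treatments if treatments is not None else ["bioturbated"] * n,
            "zone": ["PBL"] * n,
            "time_point": ["T1"] * n,
        },
        index=sample_ids,
    )
    return ZOTUTable(
        counts=pd.DataFrame(counts, index=sample_ids, columns=taxa),
        taxonomy=taxonomy,
        sample_metadata=meta,
        domain=domain,
    )


@pytest.fixture
def small_table():
    rng = np.random.default_rng(42)
    return make_table(rng.integers(0, 200, size=(8, 12)) + 1)


@pytest.fixture
def two_tip_star_tree():
    return TreeNode.read(io.StringIO("(t0:1.0,t1:1.0);"))
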