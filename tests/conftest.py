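import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def nest_csv(tmp_path):
    """A minimal nests file in the documented external header format."""
    path = tmp_path / "nests.csv"
    path.write_text(
        "codigo.i,sitio,mean.no.celd,celd.tot,nidos.tot\n"
        "Xylocopa atamisquensis,S01,3.5,7,2\n"
    )
    return path


@pytest.fixture
def small_sites_frame():
    rng = np.random.default_rng(7)
    n = 20
    elev = rng.uniform(1100, 1500, n)
    rich = 0.4 * (elev - 1300) / 115 + rng.normal(0, 0.9, n)
    return pd.DataFrame({
        "site": [f"S{i:02d}" for i in range(n)],
        "elevation": elev,
        "flower_richness": rich,
        "stability": -0.5 * rich + rng.normal(0, 0.8, n),
        "total_cells": rng.poisson(20, n).astype(float),
    })
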