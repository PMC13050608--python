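import numpy as np
import pandas as pd
import pytest

import cellpop as cp


@pytest.fixture
def f1() -> cp.Dataset:
    """2 samples x 2 cell types worked example: counts [[3,1],[0,2]]."""
    return cp.fixture_f1()


@pytest.fixture
def f1_cells() -> cp.CellTable:
    return cp.fixture_f1_cells()


def small_atlas(seed: int, **kw) -> tuple:
    """A fast synthetic atlas for randomized invariant checks."""
    defaults = dict(
        n_samples=6,
        n_celltypes=5,
        hierarchy_depth=2,
        branching=3,
        dirichlet_alpha=2.0,
        total_cells_log_mean=4.0,  # ~55 cells/sample
        total_cells_log_sd=0.5,
        absent_fraction=0.15,
        seed=seed,
    )
    defaults.update(kw)
    return cp.generate_atlas(cp.AtlasSpec(**defaults))


@pytest.fixture
def atlas():
    return small_atlas(seed=42)
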