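import numpy as np
import pandas as pd
import pytest

from grassmf import synthetic_data as sd
from grassmf.services import default_service_map


@pytest.fixture(scope="session")
def service_map():
    return default_service_map()


@pytest.fixture(scope="session")
def study_dataset():
    """One study-scale synthetic dataset (86 plots, default effects)."""
    design = sd.generate_design(seed=11)
    management = sd.generate_management(design, seed=12)
    indicators = sd.generate_indicators(design, management, seed=13)
    return design, management, indicators


@pytest.fixture(scope="session")
def large_null_dataset():
    """~400 plots with all treatment multipliers = 1 (no effects)."""
    cells = sd.scale_cells(factor=400 / 86)
    design = sd.generate_design(n_pairs=84, cell_counts=cells, seed=21)
    management = sd.generate_management(design, seed=22)
    indicators = sd.generate_indicators(design, management, sd.null_effect_spec(), seed=23)
    return design, management, indicators
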