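from datetime import date as Date

import numpy as np
import pytest

from gencmr.genotype_io import SampleRecord
from gencmr.synthetic import SimulationConfig, default_grid, default_visit_schedule

STUDY_SPECTRUM = {1: 157, 2: 25, 3: 5, 4: 2, 5: 1}


def make_sample(
    sample_id="S1",
    date=Date(2013, 7, 1),
    x=0.0,
    y=0.0,
    genotype=None,
    sex_markers=None,
    haplotype="H1",
    freshness="fresh",
):
    if genotype is None:
        genotype = {f"L{i}": (100 + 2 * i, 102 + 2 * i) for i in range(1, 9)}
    if sex_markers is None:
        sex_markers = {"SRY": "-", "AMELY": "-", "PLP1": "+"}
    return SampleRecord(
        sample_id=sample_id,
        date=date,
        x=x,
        y=y,
        genotype=genotype,
        sex_markers=sex_markers,
        haplotype=haplotype,
        freshness_class=freshness,
    )


@pytest.fixture
def small_config():
    """Compact survey: 4x4 grid, ~100 km^2 buffered, moderate density."""
    grid = default_grid(4, 2000.0)
    return SimulationConfig(
        visit_schedule=default_visit_schedule(grid, n_visits=2),
        true_density=2.0,
        lambda0=0.3,
        sigma=1200.0,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
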