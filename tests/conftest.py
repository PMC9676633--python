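import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cladediv.config import RunConfig
from cladediv.pangenome import PresenceAbsenceMatrix
from cladediv.pipeline import analyze_cohort
from cladediv.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """10-sample synthetic cohort at the default study conditions."""
    return simulate_cohort(SimulationConfig(n_samples=10, seed=7))


@pytest.fixture(scope="session")
def study_cohort():
    """The 50-sample cohort at the default study conditions (markers at e x
    the housekeeping rate, core genes at 1x)."""
    return simulate_cohort(SimulationConfig(n_samples=50, seed=11))


@pytest.fixture(scope="session")
def study_analysis(study_cohort):
    variants = {s.sample_id: s.variants for s in study_cohort.samples}
    return analyze_cohort(
        study_cohort.catalog,
        [s.coverage for s in study_cohort.samples],
        variants,
        study_cohort.metadata,
        RunConfig(n_core=60),
        compute_tajima=True,
    )


@pytest.fixture()
def toy_pam():
    """6 genomes, hand-built genes exercising marker/core/housekeeping rules."""
    genomes = [f"g{i}" for i in range(6)]
    df = pd.DataFrame(
        {
            "recA": [1, 1, 1, 1, 1, 1],       # universal housekeeping
            "markerA": [1, 1, 1, 0, 0, 0],    # clade-1 specific
            "leaky": [1, 1, 1, 1, 0, 0],      # present in both clades
            "coreish": [1, 1, 1, 1, 1, 0],    # 5/6 ~ 0.83
            "rare": [1, 0, 0, 0, 0, 0],
        },
        index=genomes,
        dtype=np.int8,
    )
    return PresenceAbsenceMatrix(df, gene_names={"recA": "recA"}, source_dialect="rtab")
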