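"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from aquaredox import synthetic_spectra as synth
from aquaredox import synthetic_trajectory as straj
from aquaredox.spectra_core import SpectraSet


@pytest.fixture(scope="session")
def gsh_series():
    """Default-noise GSH concentration series (10 levels x 25 reps)."""
    design = synth.ExperimentDesign(analytes=(synth.GSH,), seed=11)
    return synth.generate_spectra_set(design)


@pytest.fixture(scope="session")
def noiseless_design():
    return synth.ExperimentDesign(
        analytes=(synth.GSH,), noise_sd=0.0, scatter_gain_sd=0.0,
        baseline_offset_sd=0.0, baseline_slope_sd=0.0,
        replicates_per_level=2, seed=5,
    )


@pytest.fixture(scope="session")
def small_thiol_traj():
    """Thiol solute, small box, short trajectory (fast fixture)."""
    return straj.generate_solvation_trajectory(
        "thiol", n_waters=40, n_frames=150, seed=21,
    )


@pytest.fixture(scope="session")
def small_disulfide_traj():
    return straj.generate_solvation_trajectory(
        "disulfide", n_waters=40, n_frames=150, seed=22,
    )


@pytest.fixture
def tiny_set():
    """Three spectra on a five-channel grid, hand-checkable."""
    grid = np.array([1300.0, 1302.0, 1304.0, 1306.0, 1308.0])
    absorbance = np.array(
        [[1.0, 2.0, 3.0, 4.0, 5.0],
         [2.0, 4.0, 6.0, 8.0, 10.0],
         [0.5, 0.5, 1.0, 0.5, 0.5]]
    )
    meta = pd.DataFrame(
        {"id": ["a", "b", "c"], "analyte": "GSH",
         "concentration_mM": [1.0, 2.0, 3.0], "replicate": [0, 1, 2]}
    )
    return SpectraSet(grid=grid, absorbance=absorbance, meta=meta)
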