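"""Shared fixtures: tiny atlases, hand-built matrices, small synthetic cohorts."""

import numpy as np
import pytest

from subcomm.connectome_io import Cohort, ConnectivityMatrix, RegionAtlas, Subject
from subcomm.synthetic_data import SimulationConfig, generate_cohort


@pytest.fixture
def atlas3():
    return RegionAtlas(("a", "b", "c"), ("a", "b", "c"))


@pytest.fixture
def atlas_mixed():
    """Five regions, two of them subcortical (non-contiguous indices)."""
    return RegionAtlas(("r0", "s1", "r2", "s3", "r4"), ("s1", "s3"))


def make_matrix(weights, atlas, subject_id="s"):
    return ConnectivityMatrix(np.asarray(weights, dtype=float), atlas, subject_id)


@pytest.fixture
def small_cohort():
    """Fast two-group synthetic cohort (40 regions, 12+10 subjects)."""
    config = SimulationConfig(n_regions=40, n_hc=12, n_ad=10, seed=1234)
    return generate_cohort(config).cohort


def cohort_from_matrices(mats_hc, mats_ad, atlas):
    subjects = [
        Subject(f"hc{i}", "HC", ConnectivityMatrix(m, atlas, f"hc{i}"))
        for i, m in enumerate(mats_hc)
    ] + [
        Subject(f"ad{i}", "AD", ConnectivityMatrix(m, atlas, f"ad{i}"))
        for i, m in enumerate(mats_ad)
    ]
    return Cohort(subjects)
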