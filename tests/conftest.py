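import numpy as np
import pandas as pd
import pytest

from bonemap import phantom


@pytest.fixture(scope="session")
def circular_tube():
    """Straight circular tube R=1, r=0.8 mm at 25 um voxels (axis wall model)."""
    spec = phantom.PhantomSpec(
        length_mm=2.0, voxel_um=25.0, outer_a=1.0, outer_b=1.0,
        wall_thickness=0.2, wall_mode="axis", calibration_rod_values=None,
        seed=0)
    gray, binary, gt = phantom.generate_bone(spec)
    return spec, gray, binary, gt


@pytest.fixture(scope="session")
def factorial_table():
    """Balanced 2x2x3 covariate table, n=5 per cell, with a noise response."""
    _, cov = phantom.generate_cohort(phantom.CohortDesign(seed=7))
    rng = np.random.default_rng(7)
    tbl = cov.copy()
    tbl["y"] = rng.normal(size=len(tbl))
    return tbl


@pytest.fixture(scope="session")
def box_envelope():
    return np.ones((64, 64, 64), dtype=bool)
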