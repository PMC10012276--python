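"""Shared fixtures: small phantom cases generated at test time."""

import numpy as np
import pytest

from kbdose.features import compute_dptv
from kbdose.phantom import DoseEngineParams, PhantomSpec, generate_phantom, simulate_dose


SMALL_SPEC = PhantomSpec(grid_shape=(32, 32, 8), spacing=(8.0, 8.0, 6.0), seed=7)


@pytest.fixture(scope="session")
def small_case():
    """One 32x32x8 phantom with noiseless distance-driven dose attached."""
    case = generate_phantom(SMALL_SPEC)
    dptv = compute_dptv(case.rois.masks["PTV"], case.rois.body_mask, case.spacing)
    case.dose_gt = simulate_dose(case, DoseEngineParams(noise_sd=0.0), dptv)
    return case


@pytest.fixture(scope="session")
def small_dptv(small_case):
    rois = small_case.rois
    return compute_dptv(rois.masks["PTV"], rois.body_mask, rois.spacing)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
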