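"""Shared fixtures: small, fast phantom subjects on a 32^3 grid.

The 32^3 grid keeps the voxel spacing of the full-size default
(12 x 12 x 10 mm field of view scaled down to 6 x 6 x 5 mm), so distances
and decay lengths are in the same physical regime as the full phantom
while each subject simulates in well under a second.
"""

from __future__ import annotations

import numpy as np
import pytest

from vascstrata.phantom import AcquisitionParams, generate_phantom
from vascstrata.pk_fit import compute_enhancement, fit_linear_pk

SMALL_ACQ = dict(fov_mm=(6.0, 6.0, 5.0), matrix=(32, 32, 32))


def small_acq(**overrides) -> AcquisitionParams:
    kw = dict(SMALL_ACQ)
    kw.update(overrides)
    return AcquisitionParams(**kw)


@pytest.fixture(scope="session")
def noiseless_subject():
    """Noiseless 32^3 control subject, shared read-only across tests."""
    return generate_phantom(small_acq(noise_sigma=0.0, seed=3), seed=3)


@pytest.fixture(scope="session")
def noiseless_pk(noiseless_subject):
    """PK maps fitted on the noiseless subject."""
    s = noiseless_subject
    enh = compute_enhancement(s.series, s.m0, s.e_blood)
    return fit_linear_pk(enh, analysis_mask=s.gt.tumor_mask)


@pytest.fixture(scope="session")
def noisy_subject():
    """Noisy 32^3 control subject (SNR ~ 20 at the vessel wall)."""
    return generate_phantom(small_acq(noise_sigma=10.0, seed=3), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
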