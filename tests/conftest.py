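"""Shared fixtures: one calibration-grade phantom study and one small cohort.

The expensive objects (phantom pair at calibration resolution, the estimated
b-field, a seeded effect cohort) are session-scoped so the whole suite pays
for them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from bsdti import (CohortSpec, Geometry, PhantomSpec, estimate_b_field,
                   make_field, make_protocol, simulate_cohort,
                   simulate_phantom_pair)
from bsdti.bsd_calibration import BMatrixField
from bsdti.synthetic_data import FieldCorrectionTensor
from bsdti import _poly

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")

PHANTOM_SEED = 3
FIELD_SEED = 7
AMPLITUDE = 0.05


@pytest.fixture(scope="session")
def full_scheme():
    return make_protocol("1000/2000(40)")


@pytest.fixture(scope="session")
def calib_geometry():
    return Geometry.centered((32, 32, 32), 2.5)


@pytest.fixture(scope="session")
def field05(calib_geometry):
    return make_field(calib_geometry, AMPLITUDE, degree=2, seed=FIELD_SEED)


@pytest.fixture(scope="session")
def phantom_pair(field05, full_scheme):
    return simulate_phantom_pair(PhantomSpec(seed=PHANTOM_SEED), field05,
                                 full_scheme)


@pytest.fixture(scope="session")
def noise_free_phantom_pair(field05, full_scheme):
    return simulate_phantom_pair(PhantomSpec(noise_sigma=0.0, seed=PHANTOM_SEED),
                                 field05, full_scheme)


@pytest.fixture(scope="session")
def true_bfield(field05, calib_geometry, full_scheme):
    return BMatrixField.from_true_field(field05, calib_geometry, full_scheme)


@pytest.fixture(scope="session")
def calibrated_bfield(phantom_pair):
    p1, _ = phantom_pair
    return estimate_b_field(p1, PhantomSpec().d0, smooth_degree=2)


@pytest.fixture(scope="session")
def cohort_geometry():
    return Geometry.centered((18, 18, 18), 2.5)


@pytest.fixture(scope="session")
def cohort_field(cohort_geometry):
    return make_field(cohort_geometry, AMPLITUDE, degree=2, seed=FIELD_SEED)


@pytest.fixture(scope="session")
def effect_cohort(cohort_field):
    """Seeded cohort with the default group effects, 16 subjects per group."""
    scheme = make_protocol("1000(20)")
    spec = CohortSpec(n_per_group=16, seed=11)
    return simulate_cohort(spec, cohort_field, scheme), scheme


def scalar_field(geometry: Geometry, coeff: float = 0.03,
                 degree: int = 1) -> FieldCorrectionTensor:
    """Isotropic field-correction tensor L(r) = c(r) I with polynomial c - 1.

    Used where the scalar-rescale calibration is exact for any imaged object.
    """
    lo, hi = geometry.world_bounds()
    center = (lo + hi) / 2.0
    halfwidth = np.maximum((hi - lo) / 2.0, 1e-9)
    exps = _poly.monomial_exponents(degree, include_constant=False)
    rng = np.random.default_rng(1234)
    c = coeff * rng.uniform(-1, 1, size=len(exps))
    coeffs = np.zeros((len(exps), 9))
    coeffs[:, 0] = coeffs[:, 4] = coeffs[:, 8] = c
    return FieldCorrectionTensor(geometry=geometry, coeffs=coeffs,
                                 exponents=exps, center=center,
                                 halfwidth=halfwidth, amplitude=abs(coeff))
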