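"""Shared fixtures: one small synthetic phantom study reused across tests.

The phantom is a 60 mm cube of the standard 15 mm / 3 mm grid (125 vertices,
64 cells) rendered at 1 mm voxels — large enough for every pipeline property
while keeping registrations to seconds.  Expensive artifacts (simulated
pairs, registrations, the validation study) are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from gridwarp import (
    DetectionParams,
    RegistrationParams,
    bspline_register,
    build_grid_geometry,
    detect_cps,
    qa_acquisition,
    random_smooth_field,
    run_validation_study,
    simulate_pair,
)

MASTER_SEED = 7


@pytest.fixture(scope="session")
def geometry():
    return build_grid_geometry(15.0, 3.0, (60.0, 60.0, 60.0))


@pytest.fixture(scope="session")
def domain_radius(geometry):
    return float(np.linalg.norm(np.asarray(geometry.grid_extent) / 2.0))


@pytest.fixture(scope="session")
def smooth_field(domain_radius):
    """A random smooth distortion field with 2 mm peak magnitude."""
    return random_smooth_field(11, max_magnitude=2.0, domain_radius=domain_radius)


@pytest.fixture(scope="session")
def identity_pair(geometry):
    """Reference/observed pair with zero distortion (noise only)."""
    return simulate_pair(geometry, None, 1.0, seed=5)


@pytest.fixture(scope="session")
def field_pair(geometry, smooth_field):
    """Reference/observed pair warped by the known smooth field."""
    return simulate_pair(geometry, smooth_field, 1.0, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def reference_cps(identity_pair):
    return detect_cps(identity_pair[0], DetectionParams())


@pytest.fixture(scope="session")
def field_registration(field_pair):
    """Default-parameter MI registration of the known-field pair."""
    ref, obs = field_pair
    return bspline_register(ref, obs, RegistrationParams(seed=1))


@pytest.fixture(scope="session")
def fgs5_registration(field_pair):
    """Same problem at FGS = 5 mm (below the vertex spacing: overfits)."""
    ref, obs = field_pair
    return bspline_register(ref, obs, RegistrationParams(fgs=5.0, seed=1))


@pytest.fixture(scope="session")
def identity_qa(geometry, identity_pair, reference_cps):
    """Full pipeline (rigid + resample + detect + register) on the
    zero-distortion pair."""
    ref, obs = identity_pair
    return qa_acquisition(
        ref, obs, reference_cps, geometry=geometry, isocenter=geometry.centroid
    )


@pytest.fixture(scope="session")
def validation_report(geometry, domain_radius):
    """Three master-seeded random 2 mm fields through the full study."""
    fields = [
        random_smooth_field(
            int(np.random.default_rng([MASTER_SEED, i]).integers(2**31)),
            max_magnitude=2.0,
            domain_radius=domain_radius,
        )
        for i in range(3)
    ]
    return run_validation_study(geometry, fields, 1.0, master_seed=MASTER_SEED)
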