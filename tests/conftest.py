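"""Shared fixtures: phantom cases and the (expensive) default registration.

The full-pipeline registration of the default phantom is session-scoped
because several tests interrogate different aspects of the same run
(strain recovery, volume consistency, field quality).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lungstrain import aeration, phantom, registration as reg

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_case() -> phantom.PhantomCase:
    """The default phantom: noise SD 10 HU, fixed seed."""
    return phantom.generate(phantom.PhantomSpec())


@pytest.fixture(scope="session")
def noiseless_case() -> phantom.PhantomCase:
    return phantom.generate(phantom.PhantomSpec(hu_noise_sd=0.0))


@pytest.fixture(scope="session")
def registered_default(default_case):
    """Full registration of the default phantom with default settings."""
    res, jac, strain = reg.register_pair(
        default_case.ee,
        default_case.ei,
        default_case.ee_mask,
        default_case.ei_mask,
        reg.RegistrationConfig(),
    )
    return default_case, res, jac, strain


@pytest.fixture(scope="session")
def small_spec() -> phantom.PhantomSpec:
    """A coarse, fast phantom for tests that do not need the default grid."""
    return phantom.PhantomSpec(
        shape=(48, 48, 24),
        spacing=(2.0, 2.0, 5.0),
        semi_axes_mm=(36.0, 34.0, 48.0),
        hu_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def small_reg_cfg() -> reg.RegistrationConfig:
    """Registration schedule compatible with the small phantom's 5 mm slices."""
    return reg.RegistrationConfig(
        knot_spacings_mm=(26.0, 13.0, 10.0, 5.5),
        shrink_factors=(2, 1, 1, 1),  # the 5 mm slices leave little room
        pad_margin_vox=10,
        iterations=(20, 15, 10, 8),
    )


def fgas_of(case_vol, case_mask):
    return aeration.hu_to_fgas(case_vol, case_mask)
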