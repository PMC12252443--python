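import logging

import numpy as np
import pytest

from fermentforge.simulator import (
    FermentationCurve,
    KineticParams,
    ParameterDraw,
    generate_curve,
    generate_dataset,
)

logging.getLogger("fermentforge").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def nominal_draw():
    """Kinetic draw at the midpoints of the uniform ranges (the
    reference rule-chain constants: Xmax=3.5, r=0.3, S0=210, ke=0.015)."""
    return ParameterDraw.nominal(KineticParams())


@pytest.fixture(scope="session")
def clean_curve(nominal_draw):
    """Noise-free nominal curve at 5-minute sampling over 21 days."""
    return generate_curve(seed=0, noise=False, draw=nominal_draw)


@pytest.fixture(scope="session")
def noisy_curve():
    return generate_curve(seed=0, noise=True)


@pytest.fixture(scope="session")
def small_curves():
    """A small seeded training set at 30-minute sampling (fast tests)."""
    return generate_dataset(8, seed=11, duration_h=504, step_min=30)


@pytest.fixture(scope="session")
def training_curves_5min():
    """The soft-sensor study conditions: 25 seeded curves at 5-minute
    sampling over 21 days."""
    return generate_dataset(25, seed=0, duration_h=504, step_min=5)
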