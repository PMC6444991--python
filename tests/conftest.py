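"""Shared fixtures: the protocol sensor and reference synthetic curves."""

from __future__ import annotations

import numpy as np
import pytest

from epitherm.inversion import TPSModel
from epitherm.synthetic import default_sensor, generate_transient
from epitherm.tps import ThermalProperties


@pytest.fixture(scope="session")
def sensor():
    """Protocol sensor: 0.5 mm element, 0.254 mm effective radius,
    7 mW/mm^2 for 2 s."""
    return default_sensor()


@pytest.fixture(scope="session")
def porcine_props():
    """Representative porcine-skin properties used for the surrogate fits."""
    return ThermalProperties(k=0.4, alpha=0.10)


@pytest.fixture(scope="session")
def clean_curve(porcine_props, sensor):
    """Noiseless 2 s transient at 100 Hz for the representative properties."""
    return generate_transient(porcine_props, sensor)


@pytest.fixture(scope="session")
def clean_fit(clean_curve, sensor):
    """Converged fit of the noiseless reference curve (shared: fits are
    deterministic)."""
    res = TPSModel(clean_curve, sensor).fit()
    assert res.converged
    return res
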