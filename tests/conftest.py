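import numpy as np
import pytest

from modalsim import GroupSpec, MixtureComponent


@pytest.fixture
def dis2_spec():
    """Printed disease-group parameters: 6.4 +/- 4.3, clamped 0-80."""
    return GroupSpec("Dis2", "gaussian", mean=6.4, sd=4.3, low=0, high=80)


@pytest.fixture
def healthy_spec():
    return GroupSpec("Healthy", "gaussian", mean=4.5, sd=2.5, low=0, high=80)


@pytest.fixture
def bimodal_components():
    """Well-separated 50/50 mixture at +/-3 with sd 0.5."""
    return [MixtureComponent(0.5, -3.0, 0.5), MixtureComponent(0.5, 3.0, 0.5)]


@pytest.fixture
def point_mass_spec():
    """Degenerate group: every subject scores exactly 5."""
    return GroupSpec("const", "uniform", low=5, high=5)


def binom_3se(p: float, n: int) -> float:
    return 3.0 * np.sqrt(p * (1.0 - p) / n)
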