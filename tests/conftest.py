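import numpy as np
import pytest

from ftszdyn import GroundTruth, VelocityPoint


@pytest.fixture
def noiseless_gt() -> GroundTruth:
    """Ground truth with every noise channel silenced."""
    return GroundTruth(noise_a340=0.0, noise_ls=0.0, noise_frap=0.0, noise_sed=0.0)


def points_on_line(activity: float, cc: float, concs) -> list[VelocityPoint]:
    """Velocity points exactly on v = activity * max(C - cc, 0)."""
    return [
        VelocityPoint(float(c), activity * max(float(c) - cc, 0.0)) for c in concs
    ]
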