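import numpy as np
import pytest

from gngflux import IsotopologueSpectrum, SyntheticTruth


@pytest.fixture
def lactate_spectrum() -> IsotopologueSpectrum:
    return IsotopologueSpectrum("lactate", 3, [0.4, 0.3, 0.2, 0.1], is_fraction=True)


@pytest.fixture
def worked_system():
    """Small interconversion system with a known interior NNLS solution."""
    from gngflux import ContributionSystem

    return ContributionSystem(
        substrates=("lactate", "glycerol", "alanine"),
        M=np.array([[1.0, 0.5, 0.0], [0.2, 1.0, 0.0], [0.0, 0.0, 1.0]]),
        M_se=np.zeros((3, 3)),
        product="glucose",
        L=np.array([0.4, 0.3, 0.1]),
        L_se=np.zeros(3),
    )


@pytest.fixture
def default_truth() -> SyntheticTruth:
    return SyntheticTruth(seed=42)


@pytest.fixture
def noiseless_truth() -> SyntheticTruth:
    return SyntheticTruth(noise_cv=0.0, seed=7)
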