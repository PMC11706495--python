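import numpy as np
import pytest

from psgequiv.hypnogram import Hypnogram


@pytest.fixture
def toy_hypnogram() -> Hypnogram:
    """10-epoch worked example: [W,W,N1,N2,N2,N3,R,W,N2,W] with one arousal."""
    return Hypnogram(
        stages=["W", "W", "N1", "N2", "N2", "N3", "R", "W", "N2", "W"],
        arousals=[(120.0, 5.0)],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240613)
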