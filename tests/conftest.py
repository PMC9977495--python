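import numpy as np
import pytest

from fishniche.spot_detection import SpotSet


def make_spotset(coords_um, channel="test", **labels) -> SpotSet:
    """Build a SpotSet from bare (x, y) coordinates for mapping tests."""
    coords = np.asarray(coords_um, dtype=float).reshape(-1, 2)
    n = len(coords)
    return SpotSet(
        channel=channel,
        x_um=coords[:, 0],
        y_um=coords[:, 1],
        peak=np.ones(n),
        area_px=np.ones(n, dtype=int),
        **labels,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)
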