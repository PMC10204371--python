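import numpy as np
import pytest

from vfoabeta import SceneSpec, make_scene


@pytest.fixture(scope="session")
def dark_scene() -> np.ndarray:
    """A 128x128 gamma-darkened low-contrast fixture."""
    return make_scene(SceneSpec(kind="gamma_dark", width=128, height=128, gamma=2.5, seed=7))


@pytest.fixture(scope="session")
def blob_scene() -> np.ndarray:
    return make_scene(SceneSpec(kind="blobs", width=128, height=128, seed=3))
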