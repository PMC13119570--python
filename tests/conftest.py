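import numpy as np
import pytest

from coralmorph.synthetic import generate_dataset


def rasterize_disk(radius: float, frame: int = 256) -> np.ndarray:
    """Independent pixel-center disk rasterization used as an oracle."""
    yy, xx = np.mgrid[0:frame, 0:frame]
    dx = (xx + 0.5) - frame / 2.0
    dy = (yy + 0.5) - frame / 2.0
    return (dx * dx + dy * dy) <= radius * radius


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Six-fixture two-timepoint dataset (3 early, 3 late)."""
    root = tmp_path_factory.mktemp("fixtures_small")
    manifest = generate_dataset(root, 3, [0, 18], seed=11)
    return root, manifest


@pytest.fixture(scope="session")
def dataset50(tmp_path_factory):
    """Fifty-fixture dataset spanning early and late stages."""
    root = tmp_path_factory.mktemp("fixtures_50")
    manifest = generate_dataset(root, 25, [0, 18], seed=23)
    return root, manifest
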