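import numpy as np
import pytest

from histotile import TileImage, write_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def asymmetric_image(rng):
    """A generic 5x5 RGB image with no accidental symmetry."""
    px = rng.integers(0, 256, size=(5, 5, 3), dtype=np.uint8)
    # guarantee asymmetry by marking one corner uniquely
    px[0, 0] = (255, 0, 0)
    px[4, 4] = (0, 255, 0)
    px[0, 4] = (0, 0, 255)
    return TileImage(px)


def make_tree(root, spec, size=16, seed=0):
    """Write a tiny class/patient tree: spec maps class -> patient -> n_tiles.

    Tiles are small random RGB images; returns the list of created paths.
    """
    rng = np.random.default_rng(seed)
    paths = []
    for cls, patients in spec.items():
        for patient, n in patients.items():
            for i in range(n):
                px = rng.integers(0, 256, size=(size, size, 3), dtype=np.uint8)
                p = root / cls / patient / f"tile{i:03d}.png"
                write_image(TileImage(px), p)
                paths.append(p)
    return paths


@pytest.fixture
def small_tree(tmp_path):
    root = tmp_path / "data"
    make_tree(root, {"mature": {"p1": 3}, "immature": {"p2": 2}})
    return root
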