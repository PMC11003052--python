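import numpy as np
import pytest

from leukoseg.imageio_core import ClassLabel, LabeledDataset, Record, write_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_image(rng, h=8, w=8):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)


@pytest.fixture
def tiny_dataset(rng):
    """12 in-memory records, 3 per class."""
    records = [
        Record(random_image(rng, 16, 16), label, f"{label.name}/{i}.png")
        for label in ClassLabel
        for i in range(3)
    ]
    return LabeledDataset(records)


@pytest.fixture
def dataset_tree(tmp_path, rng):
    """Class-per-subdirectory tree with 3 PNGs per class."""
    for label in ClassLabel:
        d = tmp_path / label.name
        d.mkdir()
        for i in range(3):
            write_image(random_image(rng, 16, 16), d / f"img_{i}.png")
    return tmp_path
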