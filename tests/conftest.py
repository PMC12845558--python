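import numpy as np
import pytest

from tgsr.colorseg import PreprocessParams
from tgsr.synth import default_stage_specs


@pytest.fixture(scope="session")
def params() -> PreprocessParams:
    return PreprocessParams()


@pytest.fixture(scope="session")
def stage_specs():
    return default_stage_specs()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small on-disk synthetic dataset (6 stages x 8 images, 320 px)."""
    from tgsr.synth import make_dataset, read_manifest

    root = tmp_path_factory.mktemp("smallds")
    specs = default_stage_specs(image_size=(320, 320))
    manifest = make_dataset(specs, 8, seed=11, out_dir=root)
    return root, read_manifest(manifest)
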