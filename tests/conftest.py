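import pytest

from synthzoo import Generators
from synthzoo.fixtures import build_fixture_zoo, synth_image_set, toy_feature_extractor
from synthzoo.registry import load_registry

BLOB_ID = "00001_BLOB_MASS"
POLYP_ID = "00002_POLYP_MASK"
TEXTURE_ID = "00003_TEXTURE_CLASS"
INVERT_ID = "00004_INVERT_I2I"
SHIFT_ID = "00005_BLOB_MASS_SHIFT"


@pytest.fixture(scope="session")
def zoo(tmp_path_factory):
    """Fixture model zoo on disk: (registry path, package dirs)."""
    target = tmp_path_factory.mktemp("zoo")
    registry_path, packages = build_fixture_zoo(target, seed=0)
    return registry_path, packages


@pytest.fixture(scope="session")
def registry(zoo):
    return load_registry(zoo[0])


@pytest.fixture(scope="session")
def cache_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("cache")


@pytest.fixture()
def generators(zoo, cache_dir):
    return Generators(registry_source=zoo[0], cache_dir=cache_dir)


@pytest.fixture(scope="session")
def toy_extractor():
    return toy_feature_extractor()


@pytest.fixture(scope="session")
def real_images():
    """200 images from the fixture blob distribution (the 'real' set)."""
    return synth_image_set(200, seed=3)
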