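"""Contribute a model package to a registry, offline, end to end.

A contribution is validated (id pattern, entry script, generate method),
its metadata entry is assembled, the model is smoke-tested by generating
samples against the declared output contract, and only then is the entry
appended to the registry and the package zipped and handed to a
publisher. The default publisher stays on the local filesystem and emits
a JSON contribution notice instead of calling any hosting API.
"""

import shutil
import tempfile
from pathlib import Path

from synthzoo import Generators
from synthzoo.fixtures import build_fixture_zoo

workdir = Path(tempfile.mkdtemp(prefix="synthzoo_example_"))
registry_path, package_dirs = build_fixture_zoo(workdir / "zoo", seed=0)

# pretend the blob package is the user's own model
my_package = workdir / "my_model"
shutil.copytree(package_dirs[0], my_package)

generators = Generators(registry_source=registry_path, cache_dir=workdir / "cache")
print(f"registry holds {len(generators.registry)} models before contribution")

result = generators.contribute(
    model_id="00100_YOUR_MODEL",
    init_py_path=my_package / "__init__.py",
    model_weights_name="weights",
    model_weights_extension=".json",
    dependencies=["numpy"],
    image_size=(64, 64, 1),
    latent_dim=16,
    performance={"FID": 9.9},
    keywords=["mammography", "contributed"],
    title="My contributed blob model",
)
print(f"test passed: {result.test_passed}")
print(f"archive: {result.package_archive.name}")
print(f"publish receipt sha256: {result.publish_receipt['sha256'][:16]}...")

print(f"\nregistry now holds {len(generators.registry)} models; "
      "the new one generates immediately:")
samples = generators.generate("00100_YOUR_MODEL", num_samples=2, seed=1)
print(f"  {len(samples)} samples of shape {samples[0].image.shape}")
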