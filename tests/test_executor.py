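import json
import zipfile

import numpy as np
import pytest

from synthzoo import executor
from synthzoo.errors import ModelExecutionError, PackageResolutionError
from synthzoo.executor import (
    GenerationRequest,
    as_batch_iterator,
    check_dependencies,
    generate,
    get_generate_callable,
    resolve_package,
)
from synthzoo.registry import ModelMetadata, Registry

from conftest import BLOB_ID, POLYP_ID, TEXTURE_ID, INVERT_ID


class TestGenerate:
    def test_sample_count_and_declared_size(self, registry, cache_dir):
        samples = generate(
            GenerationRequest(model_id=BLOB_ID, num_samples=5, seed=1),
            registry, cache_dir,
        )
        assert len(samples) == 5
        for s in samples:
            assert s.image.shape == (64, 64, 1)
            assert s.image.dtype == np.uint8

    def test_zero_samples_is_empty(self, registry, cache_dir, tmp_path):
        out = generate(
            GenerationRequest(model_id=BLOB_ID, num_samples=0, save_images=True,
                              output_path=tmp_path / "none", seed=1),
            registry, cache_dir,
        )
        assert out == []
        assert not list((tmp_path / "none").glob("*.png"))

    @pytest.mark.parametrize("model_id", [BLOB_ID, POLYP_ID, TEXTURE_ID, INVERT_ID])
    def test_chunking_does_not_change_output(self, registry, cache_dir, model_id):
        """Batch size 3 and 10 give element-wise identical samples at a fixed seed."""
        runs = [
            generate(GenerationRequest(model_id=model_id, num_samples=10,
                                       batch_size=bs, seed=7), registry, cache_dir)
            for bs in (3, 10)
        ]
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a.image, b.image)
            assert a.label == b.label

    def test_fixed_seed_is_bit_reproducible(self, registry, cache_dir):
        req = lambda: GenerationRequest(model_id=BLOB_ID, num_samples=4, seed=11)
        a = generate(req(), registry, cache_dir)
        b = generate(req(), registry, cache_dir)
        for x, y in zip(a, b):
            assert x.image.tobytes() == y.image.tobytes()

    def test_unknown_model_raises_key_error(self, registry, cache_dir):
        with pytest.raises(KeyError):
            generate(GenerationRequest(model_id="00099_NOPE", num_samples=1),
                     registry, cache_dir)

    def test_invalid_request_parameters(self):
        with pytest.raises(ValueError):
            GenerationRequest(model_id=BLOB_ID, num_samples=-1)
        with pytest.raises(ValueError):
            GenerationRequest(model_id=BLOB_ID, num_samples=1, batch_size=0)


class TestSaveImages:
    def test_files_written_with_naming_scheme_and_manifest(self, registry, cache_dir, tmp_path):
        out = tmp_path / "samples"
        written = generate(
            GenerationRequest(model_id=BLOB_ID, num_samples=7, save_images=True,
                              output_path=out, seed=2, batch_size=3),
            registry, cache_dir,
        )
        names = sorted(p.name for p in written)
        assert names == [f"{BLOB_ID}_{i:06d}.png" for i in range(7)]
        assert len(set(names)) == 7
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["model_id"] == BLOB_ID
        assert manifest["seed"] == 2
        assert sorted(manifest["files"]) == names

    def test_masks_written_as_siblings(self, registry, cache_dir, tmp_path):
        out = tmp_path / "polyps"
        written = generate(
            GenerationRequest(model_id=POLYP_ID, num_samples=3, save_images=True,
                              output_path=out, seed=2),
            registry, cache_dir,
        )
        names = {p.name for p in written}
        assert f"{POLYP_ID}_000000_mask.png" in names
        assert len(written) == 6  # image + mask per sample

    def test_saving_keeps_at_most_one_batch_resident(self, registry, cache_dir,
                                                     tmp_path, monkeypatch):
        """The save path must be chunked: no model call exceeds batch_size."""
        calls = []
        original = executor._run_batches

        def spy(metadata, package, request, on_batch, base_offset=0):
            def wrapped(batch, offset):
                calls.append(len(batch))
                on_batch(batch, offset)
            return original(metadata, package, request, wrapped, base_offset)

        monkeypatch.setattr(executor, "_run_batches", spy)
        generate(
            GenerationRequest(model_id=BLOB_ID, num_samples=10, save_images=True,
                              output_path=tmp_path / "o", seed=0, batch_size=4),
            registry, cache_dir,
        )
        assert calls == [4, 4, 2]


class TestResolution:
    def test_local_directory_used_in_place(self, registry, cache_dir, zoo):
        entry = registry.entries[BLOB_ID]
        package = resolve_package(entry, cache_dir)
        assert package.root_dir == zoo[1][0]
        assert package.entry_script.name == "__init__.py"
        assert package.weights_path.name == "weights.json"

    def test_zip_location_fetched_and_unpacked_once(self, zoo, tmp_path):
        blob_dir = zoo[1][0]
        archive = tmp_path / "pkg.zip"
        with zipfile.ZipFile(archive, "w") as zf:
            for name in ("__init__.py", "weights.json"):
                zf.write(blob_dir / name, arcname=name)
        entry = ModelMetadata.from_dict("00090_ZIPPED_BLOB", {
            "execution": {
                "package_location": str(archive), "package_name": "zipped",
                "weights_name": "weights", "weights_extension": ".json",
                "dependencies": ["numpy"], "generate_method_name": "generate",
                "generate_args": {}, "image_size": [64, 64, 1], "latent_dim": 16,
            },
            "selection": {"performance": {}, "keywords": []},
            "description": {"title": "zipped"},
        })
        fetches = []

        def spy_fetcher(uri):
            fetches.append(uri)
            return archive.read_bytes()

        cache = tmp_path / "cache"
        first = resolve_package(entry, cache, fetcher=spy_fetcher)
        assert first.entry_script.is_file()
        assert fetches == [str(archive)]
        second = resolve_package(entry, cache, fetcher=spy_fetcher)
        assert fetches == [str(archive)]  # cache hit, no refetch
        assert second.entry_script == first.entry_script

    def test_archive_without_entry_script_rejected(self, tmp_path):
        archive = tmp_path / "bad.zip"
        with zipfile.ZipFile(archive, "w") as zf:
            zf.writestr("readme.txt", "no entry script here")
        entry = ModelMetadata.from_dict("00091_BAD_PKG", {
            "execution": {"package_location": str(archive), "package_name": "bad",
                          "generate_method_name": "generate",
                          "image_size": [1, 1, 1]},
            "selection": {}, "description": {"title": "bad"},
        })
        with pytest.raises(PackageResolutionError, match="entry script"):
            resolve_package(entry, tmp_path / "cache", fetcher=lambda u: archive.read_bytes())

    def test_lazy_loading_no_fetch_before_first_generate(self, zoo, tmp_path):
        from synthzoo import Generators

        fetches = []
        g = Generators(registry_source=zoo[0], cache_dir=tmp_path / "c",
                       fetcher=lambda u: fetches.append(u) or b"")
        g.find_model(["mammography"], "OR")
        g.rank_models_by_performance(metric="FID")
        assert fetches == []


class TestDependencies:
    def test_present_dependency_satisfied(self, registry):
        report = check_dependencies(registry.entries[BLOB_ID])
        assert report.missing == []
        assert report.satisfied == ["numpy"]

    def test_absent_dependency_reported_missing(self):
        entry = ModelMetadata.from_dict("00092_DEPS", {
            "execution": {"dependencies": ["numpy", "no_such_pkg_xyz>=1.0"],
                          "generate_method_name": "g", "image_size": [1, 1, 1]},
            "selection": {}, "description": {"title": "d"},
        })
        report = check_dependencies(entry)
        assert report.missing == ["no_such_pkg_xyz>=1.0"]
        assert set(report.required) == set(report.satisfied) | set(report.missing)

    def test_installer_invoked_for_missing_only(self):
        entry = ModelMetadata.from_dict("00092_DEPS", {
            "execution": {"dependencies": ["numpy", "no_such_pkg_xyz"],
                          "generate_method_name": "g", "image_size": [1, 1, 1]},
            "selection": {}, "description": {"title": "d"},
        })
        installed = []
        report = check_dependencies(entry, install=True, installer=installed.append)
        assert installed == ["no_such_pkg_xyz"]
        assert report.installed_now == ["no_such_pkg_xyz"]


class TestCallableAndIterator:
    def test_callable_generates_without_rereolution(self, registry, cache_dir):
        call = get_generate_callable(BLOB_ID, registry, cache_dir)
        assert len(call(3, seed=1)) == 3

    def test_condition_override_reflected_in_labels(self, registry, cache_dir):
        call = get_generate_callable(TEXTURE_ID, registry, cache_dir)
        labels = {s.label for s in call(6, seed=1, condition=1)}
        assert labels == {1}

    def test_callables_for_different_models_independent(self, registry, cache_dir):
        blob = get_generate_callable(BLOB_ID, registry, cache_dir)
        polyp = get_generate_callable(POLYP_ID, registry, cache_dir)
        assert blob(1, seed=0)[0].mask is None
        assert polyp(1, seed=0)[0].mask is not None

    def test_finite_iterator_batch_arithmetic(self, registry, cache_dir):
        batches = list(as_batch_iterator(BLOB_ID, registry, cache_dir,
                                         batch_size=4, length=10, seed=0))
        assert [len(b) for b in batches] == [4, 4, 2]

    def test_transform_applied(self, registry, cache_dir):
        it = as_batch_iterator(BLOB_ID, registry, cache_dir, batch_size=2, length=2,
                               transform=lambda s: s.image.astype(float) / 255.0,
                               seed=0)
        batch = next(iter(it))
        assert all(0.0 <= b.min() and b.max() <= 1.0 for b in batch)

    def test_same_seed_same_first_batch(self, registry, cache_dir):
        first = next(iter(as_batch_iterator(BLOB_ID, registry, cache_dir,
                                            batch_size=3, seed=5)))
        second = next(iter(as_batch_iterator(BLOB_ID, registry, cache_dir,
                                             batch_size=3, seed=5)))
        for a, b in zip(first, second):
            np.testing.assert_array_equal(a.image, b.image)

    def test_bad_batch_size_rejected(self, registry, cache_dir):
        with pytest.raises(ValueError):
            next(as_batch_iterator(BLOB_ID, registry, cache_dir, batch_size=0))


class TestErrorWrapping:
    def test_model_exception_carries_id_and_batch_index(self, tmp_path):
        pkg = tmp_path / "raising"
        pkg.mkdir()
        (pkg / "__init__.py").write_text(
            "def generate(model_file=None, num_samples=1, save_images=False,\n"
            "             output_path=None, seed=0, sample_offset=0, **kw):\n"
            "    if sample_offset >= 2:\n"
            "        raise RuntimeError('boom at sample 2')\n"
            "    return [{'image': __import__('numpy').zeros((4, 4, 1), 'uint8')}\n"
            "            for _ in range(num_samples)]\n"
        )
        entry = ModelMetadata.from_dict("00093_RAISER", {
            "execution": {"package_location": str(pkg), "package_name": "raising",
                          "generate_method_name": "generate",
                          "image_size": [4, 4, 1]},
            "selection": {}, "description": {"title": "raiser"},
        })
        registry = Registry(entries={entry.model_id: entry})
        with pytest.raises(ModelExecutionError) as exc:
            generate(GenerationRequest(model_id=entry.model_id, num_samples=6,
                                       batch_size=2, seed=0),
                     registry, tmp_path / "cache")
        assert exc.value.model_id == "00093_RAISER"
        assert exc.value.batch_index == 1
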