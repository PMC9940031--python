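"""Resolve, import, and run model packages to generate synthetic samples.

A model package is an ordinary directory holding an entry script
(``__init__.py``) and, for learned models, a weights file. The entry
script exposes a generate function, named in the registry metadata, with
the standardized signature::

    def generate(model_file, num_samples, save_images, output_path,
                 seed=None, sample_offset=0, **kwargs):
        ...
        return [{"image": array, "mask": ..., "label": ...}, ...]

``kwargs`` carries optional model-specific inputs such as
``input_latent_vector`` (GAN latent z), ``condition`` (class label), or
``input_images`` (image-to-image translation). Determinism contract:
sample ``i`` of a request derives all its randomness from the pair
``(seed, sample_offset + i)`` — a counter-based keying that makes output
independent of how the request is chunked into batches.

Resolution is lazy and cached: nothing is fetched or imported until the
first generation request for a model id, and a second request reuses the
unpacked package. Remote locations go through a pluggable ``fetcher``
(URI -> bytes); local directories are used in place.
"""

from __future__ import annotations

import importlib.util
import io
import json
import logging
import sys
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterator
from urllib.request import urlopen

import numpy as np
from PIL import Image

from .errors import (
    DependencyError,
    ModelExecutionError,
    PackageResolutionError,
)
from .registry import ModelMetadata, Registry, get_metadata

logger = logging.getLogger(__name__)

DEFAULT_BATCH_SIZE = 32


# ---------------------------------------------------------------------------
# containers


@dataclass
class ModelPackage:
    """A resolved, importable generator package."""

    root_dir: Path
    entry_script: Path
    generate_callable_name: str
    weights_path: Path | None
    resolved_from: str


@dataclass
class GenerationRequest:
    """Parameters of one generation run."""

    model_id: str
    num_samples: int
    save_images: bool = False
    output_path: str | Path | None = None
    install_dependencies: bool = False
    batch_size: int = DEFAULT_BATCH_SIZE
    seed: int | None = None
    extra_args: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.num_samples < 0:
            raise ValueError("num_samples must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class SampleItem:
    """One generated output: image plus optional mask/label and a filename."""

    image: np.ndarray
    mask: np.ndarray | None = None
    label: Any = None
    filename: str = ""


@dataclass
class DependencyReport:
    required: list[str]
    satisfied: list[str]
    missing: list[str]
    installed_now: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# fetching and resolution


def default_fetcher(uri: str) -> bytes:
    """Read bytes from a file path or a file://, http(s):// URI."""
    if "://" in uri:
        with urlopen(uri) as resp:  # noqa: S310 - scheme chosen by the registry
            return resp.read()
    return Path(uri).read_bytes()


_resolved: dict[tuple[str, str], ModelPackage] = {}
_imported: dict[str, Any] = {}


def clear_caches() -> None:
    """Forget resolved packages and imported entry modules (test hook)."""
    _resolved.clear()
    _imported.clear()


def _find_entry(root: Path, package_name: str) -> Path:
    candidates = [
        root / package_name / "__init__.py",
        root / "__init__.py",
    ]
    for cand in candidates:
        if cand.is_file():
            return cand
    raise PackageResolutionError(
        f"no entry script found under {root} (looked for "
        f"{package_name}/__init__.py and __init__.py)"
    )


def resolve_package(
    metadata: ModelMetadata,
    cache_dir: str | Path,
    fetcher: Callable[[str], bytes] | None = None,
) -> ModelPackage:
    """Materialize a model package locally and locate its entry script.

    Local directories are used in place (no copy). Anything else is
    fetched as bytes, treated as a ZIP archive, and unpacked under
    ``cache_dir/<model_id>``. Idempotent: an already-unpacked package is
    reused without calling the fetcher again.
    """
    cache_dir = Path(cache_dir)
    key = (str(cache_dir), metadata.model_id)
    if key in _resolved:
        return _resolved[key]
    fetcher = fetcher or default_fetcher
    ex = metadata.execution
    location = ex.package_location

    local = Path(location) if "://" not in location else None
    if local is not None and local.is_dir():
        root = local
        resolved_from = str(local)
    else:
        root = cache_dir / metadata.model_id
        if not root.is_dir():
            try:
                blob = fetcher(location)
            except PackageResolutionError:
                raise
            except Exception as e:
                raise PackageResolutionError(
                    f"could not fetch package for {metadata.model_id} "
                    f"from {location!r}: {e}"
                ) from e
            root.mkdir(parents=True, exist_ok=True)
            try:
                with zipfile.ZipFile(io.BytesIO(blob)) as zf:
                    zf.extractall(root)
            except zipfile.BadZipFile as e:
                raise PackageResolutionError(
                    f"package for {metadata.model_id} is not a ZIP archive"
                ) from e
        resolved_from = location

    entry = _find_entry(root, ex.package_name)
    weights = None
    if ex.weights_name:
        weights = entry.parent / f"{ex.weights_name}{ex.weights_extension}"
        if not weights.is_file():
            raise PackageResolutionError(
                f"weights file {weights.name} missing in package of {metadata.model_id}"
            )
    package = ModelPackage(
        root_dir=root,
        entry_script=entry,
        generate_callable_name=ex.generate_method_name,
        weights_path=weights,
        resolved_from=resolved_from,
    )
    _resolved[key] = package
    return package


# ---------------------------------------------------------------------------
# dependencies


def _dep_name(spec: str) -> str:
    for sep in ("==", ">=", "<=", "~=", ">", "<", "!="):
        if sep in spec:
            return spec.split(sep)[0].strip()
    return spec.strip()


def check_dependencies(
    metadata: ModelMetadata,
    install: bool = False,
    installer: Callable[[str], None] | None = None,
) -> DependencyReport:
    """Probe each declared dependency for import presence.

    Version specifiers are recorded but not enforced (presence-only
    probe). With ``install=True`` the pluggable installer is invoked for
    the missing ones only.
    """
    required = list(metadata.execution.dependencies)
    satisfied, missing = [], []
    for spec in required:
        name = _dep_name(spec)
        if importlib.util.find_spec(name.replace("-", "_")) is not None:
            satisfied.append(spec)
        else:
            missing.append(spec)
    installed_now: list[str] = []
    if install and missing:
        if installer is None:
            raise DependencyError(
                f"missing dependencies {missing} and no installer provided"
            )
        for spec in list(missing):
            try:
                installer(spec)
            except Exception as e:
                raise DependencyError(f"failed to install {spec!r}: {e}") from e
            installed_now.append(spec)
    return DependencyReport(
        required=required, satisfied=satisfied, missing=missing,
        installed_now=installed_now,
    )


# ---------------------------------------------------------------------------
# import and invocation


def _import_entry(package: ModelPackage, model_id: str):
    key = str(package.entry_script)
    if key in _imported:
        return _imported[key]
    mod_name = f"synthzoo_models.{model_id.lower()}"
    spec = importlib.util.spec_from_file_location(mod_name, package.entry_script)
    if spec is None or spec.loader is None:
        raise PackageResolutionError(f"cannot import entry script {package.entry_script}")
    module = importlib.util.module_from_spec(spec)
    sys.modules[mod_name] = module
    spec.loader.exec_module(module)
    _imported[key] = module
    return module


def _get_callable(package: ModelPackage, model_id: str) -> Callable[..., Any]:
    module = _import_entry(package, model_id)
    try:
        return getattr(module, package.generate_callable_name)
    except AttributeError:
        raise PackageResolutionError(
            f"entry script of {model_id} has no callable "
            f"{package.generate_callable_name!r}"
        ) from None


def _as_sample(raw: Any, metadata: ModelMetadata) -> SampleItem:
    if isinstance(raw, SampleItem):
        return raw
    if isinstance(raw, dict):
        return SampleItem(
            image=np.asarray(raw["image"]),
            mask=None if raw.get("mask") is None else np.asarray(raw["mask"]),
            label=raw.get("label"),
        )
    return SampleItem(image=np.asarray(raw))


def _save_sample(sample: SampleItem, out_dir: Path, model_id: str, index: int) -> list[str]:
    """Write one sample as 8-bit PNG (grayscale or RGB); returns filenames."""
    img = np.asarray(sample.image)
    if img.ndim == 3 and img.shape[2] == 1:
        img = img[:, :, 0]
    arr = np.clip(img, 0, 255).astype(np.uint8)
    name = f"{model_id}_{index:06d}.png"
    Image.fromarray(arr).save(out_dir / name)
    written = [name]
    sample.filename = name
    if sample.mask is not None:
        mask = np.clip(np.asarray(sample.mask), 0, 255).astype(np.uint8)
        mask_name = f"{model_id}_{index:06d}_mask.png"
        Image.fromarray(mask).save(out_dir / mask_name)
        written.append(mask_name)
    return written


def _run_batches(
    metadata: ModelMetadata,
    package: ModelPackage,
    request: GenerationRequest,
    on_batch: Callable[[list[SampleItem], int], None],
    base_offset: int = 0,
) -> None:
    """Invoke the model callable in ceil(n/batch) chunks."""
    fn = _get_callable(package, metadata.model_id)
    seed = request.seed
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
        logger.info("no seed given for %s; drew %d", metadata.model_id, seed)
    defaults = dict(metadata.execution.generate_args)
    defaults.update(request.extra_args)
    model_file = str(package.weights_path) if package.weights_path else None

    produced = 0
    batch_index = 0
    while produced < request.num_samples:
        count = min(request.batch_size, request.num_samples - produced)
        try:
            raw = fn(
                model_file=model_file,
                num_samples=count,
                save_images=False,
                output_path=None,
                seed=seed,
                sample_offset=base_offset + produced,
                **defaults,
            )
        except Exception as e:
            raise ModelExecutionError(metadata.model_id, batch_index, e) from e
        batch = [_as_sample(r, metadata) for r in raw]
        if len(batch) != count:
            raise ModelExecutionError(
                metadata.model_id, batch_index,
                AssertionError(f"model returned {len(batch)} samples, expected {count}"),
            )
        on_batch(batch, produced)
        produced += count
        batch_index += 1


def generate(
    request: GenerationRequest,
    registry: Registry,
    cache_dir: str | Path | None = None,
    fetcher: Callable[[str], bytes] | None = None,
    installer: Callable[[str], None] | None = None,
) -> list[SampleItem] | list[Path]:
    """Generate ``num_samples`` samples from a registered model.

    Runs in ``ceil(num_samples / batch_size)`` chunks; with a fixed seed
    the output is identical across runs and across batch sizes. With
    ``save_images`` the samples are written as PNGs named
    ``{model_id}_{index:06d}.png`` (masks as ``_mask.png`` siblings) plus
    a ``manifest.json``, keeping at most one batch in memory; otherwise
    the samples are returned as a list.
    """
    metadata = get_metadata(registry, request.model_id)
    cache_dir = Path(cache_dir) if cache_dir is not None else Path(".synthzoo_cache")
    package = resolve_package(metadata, cache_dir, fetcher)
    report = check_dependencies(metadata, request.install_dependencies, installer)
    if report.missing and not request.install_dependencies:
        logger.warning(
            "model %s has unsatisfied dependencies: %s", request.model_id, report.missing
        )

    if not request.save_images:
        collected: list[SampleItem] = []
        _run_batches(metadata, package, request, lambda batch, _: collected.extend(batch))
        return collected

    out_dir = Path(request.output_path or Path("synthzoo_samples") / request.model_id)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest_files: list[str] = []

    def save_batch(batch: list[SampleItem], offset: int) -> None:
        for j, sample in enumerate(batch):
            names = _save_sample(sample, out_dir, request.model_id, offset + j)
            manifest_files.extend(names)
            written.extend(out_dir / n for n in names)

    _run_batches(metadata, package, request, save_batch)
    manifest = {
        "model_id": request.model_id,
        "num_samples": request.num_samples,
        "seed": request.seed,
        "files": manifest_files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return written


def get_generate_callable(
    model_id: str,
    registry: Registry,
    cache_dir: str | Path | None = None,
    frozen_defaults: dict[str, Any] | None = None,
    fetcher: Callable[[str], bytes] | None = None,
) -> Callable[..., list[SampleItem]]:
    """Return a closure generating samples without re-resolving the package.

    The closure takes ``num_samples`` plus keyword overrides merged over
    the frozen defaults (which themselves override the metadata's
    declared generate-arg defaults).
    """
    metadata = get_metadata(registry, model_id)
    cache = Path(cache_dir) if cache_dir is not None else Path(".synthzoo_cache")
    package = resolve_package(metadata, cache, fetcher)
    frozen = dict(frozen_defaults or {})

    def call(
        num_samples: int,
        seed: int | None = None,
        sample_offset: int = 0,
        **overrides,
    ) -> list[SampleItem]:
        extra = dict(frozen)
        extra.update(overrides)
        request = GenerationRequest(
            model_id=model_id, num_samples=num_samples, seed=seed, extra_args=extra,
        )
        collected: list[SampleItem] = []
        _run_batches(
            metadata, package, request,
            lambda batch, _: collected.extend(batch),
            base_offset=sample_offset,
        )
        return collected

    return call


def as_batch_iterator(
    model_id: str,
    registry: Registry,
    cache_dir: str | Path | None = None,
    batch_size: int = DEFAULT_BATCH_SIZE,
    transform: Callable[[SampleItem], Any] | None = None,
    length: int | None = None,
    seed: int | None = 0,
) -> Iterator[list[Any]]:
    """Yield batches of samples, ready for a training loop.

    Infinite by default; with ``length`` set, yields
    ``ceil(length / batch_size)`` batches, the last possibly smaller.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    call = get_generate_callable(model_id, registry, cache_dir)
    offset = 0
    while True:
        if length is not None:
            remaining = length - offset
            if remaining <= 0:
                return
            count = min(batch_size, remaining)
        else:
            count = batch_size
        # continue the (seed, index) stream across yielded batches
        batch = call(count, seed=seed, sample_offset=offset)
        if transform is not None:
            batch = [transform(s) for s in batch]
        yield batch
        offset += count
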