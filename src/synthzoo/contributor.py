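"""Contribution workflow: validate, test, package, and register a model.

A contribution starts from a local package directory (an ``__init__.py``
entry script plus optional weights). The workflow (i) validates the
proposed model id and package layout, (ii) assembles the three-section
metadata entry, (iii) runs an end-to-end generation test against the
declared output contract, and (iv) appends the entry to the registry
file and zips the package for publication.

Publishing is behind the :class:`Publisher` contract. The default
:class:`FilesystemPublisher` writes the archive and a JSON contribution
notice (the offline analogue of opening an issue with the hosting
metadata) to a local directory and returns a deterministic receipt, so
the whole workflow runs without network access; an API-backed publisher
can be plugged in without touching the rest of the workflow.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import importlib.util
import inspect
import json
import logging
import shutil
import tempfile
import traceback
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Protocol

import numpy as np

from . import executor as _executor
from .errors import ConflictError, ContributionError
from .registry import (
    ModelMetadata,
    Registry,
    is_valid_model_id,
    load_registry,
    validate_metadata,
    write_registry,
)

logger = logging.getLogger(__name__)

ENTRY_SCRIPT_NAME = "__init__.py"


@dataclass
class ContributionRequest:
    """Everything a contributor supplies about a new model."""

    model_id: str
    init_script_path: str | Path
    generate_method_name: str = "generate"
    weights_name: str = ""
    weights_extension: str = ""
    dependencies: list[str] = field(default_factory=list)
    image_size: tuple[int, int, int] = (64, 64, 1)
    latent_dim: int | None = None
    extra_metadata: dict[str, Any] = field(default_factory=dict)


@dataclass
class ContributionResult:
    metadata_entry: ModelMetadata
    package_archive: Path
    test_passed: bool
    publish_receipt: dict[str, Any] = field(default_factory=dict)


class Publisher(Protocol):
    def publish(self, archive: Path, entry: ModelMetadata) -> dict[str, Any]: ...


class FilesystemPublisher:
    """Offline publisher: copies the archive and writes a notice file."""

    def __init__(self, destination: str | Path):
        self.destination = Path(destination)

    def publish(self, archive: Path, entry: ModelMetadata) -> dict[str, Any]:
        self.destination.mkdir(parents=True, exist_ok=True)
        target = self.destination / archive.name
        shutil.copyfile(archive, target)
        digest = hashlib.sha256(target.read_bytes()).hexdigest()
        notice = {
            "model_id": entry.model_id,
            "archive": target.name,
            "sha256": digest,
            "metadata": entry.to_dict(),
        }
        notice_path = self.destination / f"{entry.model_id}_notice.json"
        notice_path.write_text(json.dumps(notice, indent=2) + "\n")
        return {"model_id": entry.model_id, "archive": str(target), "sha256": digest,
                "notice": str(notice_path)}


# ---------------------------------------------------------------------------
# validation


def validate_contribution(request: ContributionRequest) -> list[str]:
    """Check a contribution request; return violation messages (empty = ok)."""
    v: list[str] = []
    if not is_valid_model_id(request.model_id):
        v.append(
            f"model_id: {request.model_id!r} does not match pattern "
            r"^\d{5}(_[A-Z0-9]+)+$"
        )
    init_path = Path(request.init_script_path)
    if init_path.name != ENTRY_SCRIPT_NAME:
        v.append(f"init_script_path: must end with {ENTRY_SCRIPT_NAME}, got {init_path.name!r}")
    if not init_path.is_file():
        v.append(f"init_script_path: {init_path} does not exist")
        return v  # nothing more to probe
    try:
        spec = importlib.util.spec_from_file_location(
            f"synthzoo_contrib.{request.model_id.lower()}", init_path
        )
        module = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(module)
    except Exception as e:
        v.append(f"package import: entry script failed to import ({e!r})")
        return v
    fn = getattr(module, request.generate_method_name, None)
    if fn is None or not callable(fn):
        v.append(
            f"generate_method_name: entry script exposes no callable "
            f"{request.generate_method_name!r}"
        )
        return v
    params = inspect.signature(fn).parameters
    if "output_path" not in params and not any(
        p.kind is inspect.Parameter.VAR_KEYWORD for p in params.values()
    ):
        v.append(
            "generate method: missing the synthetic-data storage path "
            "parameter 'output_path'"
        )
    return v


# ---------------------------------------------------------------------------
# metadata assembly


def build_metadata_entry(
    request: ContributionRequest,
    measured: dict[str, Any] | None = None,
) -> ModelMetadata:
    """Assemble a three-section entry for a validated request.

    Description fields default sensibly (title from the model id, date
    today in ISO-8601); a measured performance map is copied into the
    selection section.
    """
    violations = validate_contribution(request)
    if violations:
        raise ContributionError(
            "cannot build metadata for an invalid contribution:\n" + "\n".join(violations)
        )
    extra = request.extra_metadata
    init_path = Path(request.init_script_path)
    entry = ModelMetadata.from_dict(request.model_id, {
        "execution": {
            "package_location": str(init_path.parent),
            "package_name": init_path.parent.name,
            "weights_name": request.weights_name,
            "weights_extension": request.weights_extension,
            "dependencies": list(request.dependencies),
            "generate_method_name": request.generate_method_name,
            "generate_args": dict(extra.get("generate_args", {})),
            "image_size": list(request.image_size),
            **({"latent_dim": request.latent_dim} if request.latent_dim else {}),
        },
        "selection": {
            "performance": dict(measured or {}),
            "keywords": [str(k).lower() for k in extra.get("keywords", [])],
        },
        "description": {
            "title": extra.get("title", request.model_id.replace("_", " ").title()),
            "modality": extra.get("modality", ""),
            "output_type": extra.get("output_type", "image"),
            "training_dataset": extra.get("training_dataset", ""),
            "license": extra.get("license", ""),
            "date": extra.get("date", _dt.date.today().isoformat()),
            "publication": extra.get("publication", ""),
        },
    })
    remaining = validate_metadata(entry)
    if remaining:
        raise ContributionError("assembled metadata is invalid: " + "; ".join(remaining))
    return entry


# ---------------------------------------------------------------------------
# end-to-end test


def test_model(
    entry: ModelMetadata,
    cache_dir: str | Path | None = None,
    n_samples: int = 3,
) -> tuple[bool, list[str]]:
    """Generate a few samples and check them against the declared contract.

    Passes iff the sample count, image dimensions, and pixel value range
    all match the metadata. Returns ``(passed, log)`` with one log line
    per check; a generation exception fails the test with the captured
    traceback in the log.
    """
    log: list[str] = []
    registry = Registry(entries={entry.model_id: entry}, source="<in-memory>")
    with tempfile.TemporaryDirectory() as tmp:
        try:
            samples = _executor.generate(
                _executor.GenerationRequest(
                    model_id=entry.model_id, num_samples=n_samples, seed=0,
                ),
                registry, cache_dir or tmp,
            )
        except Exception:
            log.append("generation: FAIL\n" + traceback.format_exc())
            return False, log
    passed = True
    if len(samples) == n_samples:
        log.append(f"sample count: OK ({n_samples})")
    else:
        log.append(f"sample count: FAIL (expected {n_samples}, got {len(samples)})")
        passed = False
    expected = tuple(entry.execution.image_size)
    lo, hi = entry.execution.value_range
    for i, sample in enumerate(samples):
        img = np.asarray(sample.image)
        shape = img.shape if img.ndim == 3 else (*img.shape, 1)
        if shape != expected:
            log.append(f"sample {i} dimensions: FAIL (declared {expected}, got {shape})")
            passed = False
        else:
            log.append(f"sample {i} dimensions: OK {shape}")
        if img.size and (img.min() < lo or img.max() > hi):
            log.append(
                f"sample {i} value range: FAIL (declared [{lo}, {hi}], "
                f"observed [{img.min()}, {img.max()}])"
            )
            passed = False
        else:
            log.append(f"sample {i} value range: OK within [{lo}, {hi}]")
        if sample.mask is not None:
            if np.asarray(sample.mask).shape[:2] != expected[:2]:
                log.append(f"sample {i} mask congruence: FAIL")
                passed = False
            else:
                log.append(f"sample {i} mask congruence: OK")
    return passed, log


test_model.__test__ = False  # not a pytest case despite the domain name


# ---------------------------------------------------------------------------
# registration and packaging


def _zip_package(entry: ModelMetadata, package_dir: Path, archive_path: Path,
                 strict: bool) -> None:
    members = [ENTRY_SCRIPT_NAME]
    if entry.execution.weights_name:
        members.append(f"{entry.execution.weights_name}{entry.execution.weights_extension}")
    for optional in ("LICENSE", "requirements.txt"):
        if (package_dir / optional).is_file():
            members.append(optional)
        elif strict:
            raise ContributionError(f"strict mode: package lacks {optional}")
        else:
            warnings.warn(f"package of {entry.model_id} lacks {optional}", stacklevel=3)
    with zipfile.ZipFile(archive_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(members):  # fixed member order
            src = package_dir / name
            if not src.is_file():
                raise ContributionError(f"package member {name} missing in {package_dir}")
            zf.write(src, arcname=name)


def register_and_package(
    entry: ModelMetadata,
    registry_path: str | Path,
    package_dir: str | Path,
    publisher: Publisher | None = None,
    cache_dir: str | Path | None = None,
    strict: bool = False,
) -> ContributionResult:
    """Test, append to the registry, zip, and publish one model.

    The registry update is append-only: a duplicate id raises
    :class:`ConflictError` and the file is left untouched; writes go
    through a temporary file so a failure cannot corrupt the registry.
    The end-to-end generation test must pass before anything is written.
    """
    registry_path = Path(registry_path)
    package_dir = Path(package_dir)

    passed, log = test_model(entry, cache_dir)
    if not passed:
        raise ContributionError(
            "model test failed; not registering:\n" + "\n".join(log)
        )

    if registry_path.exists():
        registry = load_registry(registry_path)
    else:
        registry = Registry(entries={}, source=str(registry_path))
    if entry.model_id in registry:
        raise ConflictError(f"model id {entry.model_id} already registered")
    registry.entries[entry.model_id] = entry

    tmp = registry_path.with_suffix(".json.tmp")
    try:
        write_registry(registry, tmp)
        tmp.replace(registry_path)
    except Exception:
        tmp.unlink(missing_ok=True)
        raise

    archive = registry_path.parent / f"{entry.model_id}.zip"
    _zip_package(entry, package_dir, archive, strict)

    publisher = publisher or FilesystemPublisher(registry_path.parent / "published")
    receipt = publisher.publish(archive, entry)
    logger.info("contributed %s: archive=%s", entry.model_id, archive)
    return ContributionResult(
        metadata_entry=entry, package_archive=archive, test_passed=True,
        publish_receipt=receipt,
    )
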