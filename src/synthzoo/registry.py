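"""Model-metadata registry.

A registry is a single UTF-8 JSON object whose top-level keys are model ids
and whose values hold three sections:

``execution``
    everything needed to resolve and run the model package (location,
    entry-script package name, weights file, dependencies, the name of the
    generate callable, its default arguments, and the declared output
    image size).
``selection``
    quantitative metrics (e.g. FID scores) and keywords used for search,
    comparison, and ranking.
``description``
    human-facing details: title, modality, output type, training dataset,
    license, date, related publication.

Model ids follow the convention ``NNNNN_TOKEN[_TOKEN...]`` — a five-digit
zero-padded ordinal followed by one or more uppercase alphanumeric tokens,
e.g. ``00010_FASTGAN_POLYPS``. Ids are case-sensitive. The serialized
shape is documented in ``data/registry.schema.json``.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

from .errors import RegistryParseError, RegistryValidationError, UnknownModelError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

MODEL_ID_PATTERN = re.compile(r"^\d{5}(_[A-Z0-9]+)+$")

#: Path of the bundled catalog of published models (with reported FID metrics).
BUNDLED_ZOO = Path(__file__).parent / "data" / "model_zoo.json"


def is_valid_model_id(model_id: str) -> bool:
    return bool(MODEL_ID_PATTERN.match(model_id))


# ---------------------------------------------------------------------------
# sections


@dataclass
class ExecutionSection:
    """How to obtain and run one model package."""

    package_location: str = ""
    package_name: str = ""
    weights_name: str = ""
    weights_extension: str = ""
    dependencies: list[str] = field(default_factory=list)
    generate_method_name: str = "generate"
    generate_args: dict[str, Any] = field(default_factory=dict)
    image_size: tuple[int, int, int] = (0, 0, 0)
    # optional capabilities
    latent_dim: int | None = None          # size of z for noise-to-image models
    value_range: tuple[float, float] = (0.0, 255.0)  # declared output pixel range

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExecutionSection":
        return cls(
            package_location=d.get("package_location", ""),
            package_name=d.get("package_name", ""),
            weights_name=d.get("weights_name", ""),
            weights_extension=d.get("weights_extension", ""),
            dependencies=list(d.get("dependencies", [])),
            generate_method_name=d.get("generate_method_name", "generate"),
            generate_args=dict(d.get("generate_args", {})),
            image_size=tuple(d.get("image_size", (0, 0, 0))),
            latent_dim=d.get("latent_dim"),
            value_range=tuple(d.get("value_range", (0.0, 255.0))),
        )

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "package_location": self.package_location,
            "package_name": self.package_name,
            "weights_name": self.weights_name,
            "weights_extension": self.weights_extension,
            "dependencies": list(self.dependencies),
            "generate_method_name": self.generate_method_name,
            "generate_args": dict(self.generate_args),
            "image_size": list(self.image_size),
        }
        if self.latent_dim is not None:
            out["latent_dim"] = self.latent_dim
        if tuple(self.value_range) != (0.0, 255.0):
            out["value_range"] = list(self.value_range)
        return out


@dataclass
class SelectionSection:
    """Metrics and keywords used for search, comparison, and ranking."""

    performance: dict[str, Any] = field(default_factory=dict)
    keywords: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SelectionSection":
        return cls(
            performance=dict(d.get("performance", {})),
            keywords=list(d.get("keywords", [])),
        )

    def to_dict(self) -> dict[str, Any]:
        return {"performance": dict(self.performance), "keywords": list(self.keywords)}


@dataclass
class DescriptionSection:
    """Human-facing details about the model."""

    title: str = ""
    modality: str = ""
    output_type: str = ""
    training_dataset: str = ""
    license: str = ""
    date: str = ""
    publication: str = ""

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DescriptionSection":
        return cls(**{k: d.get(k, "") for k in (
            "title", "modality", "output_type", "training_dataset",
            "license", "date", "publication")})

    def to_dict(self) -> dict[str, Any]:
        return {
            "title": self.title,
            "modality": self.modality,
            "output_type": self.output_type,
            "training_dataset": self.training_dataset,
            "license": self.license,
            "date": self.date,
            "publication": self.publication,
        }


@dataclass
class ModelMetadata:
    """One registry entry: id plus the three metadata sections."""

    model_id: str
    execution: ExecutionSection
    selection: SelectionSection
    description: DescriptionSection
    # sections present in the raw JSON (used to report missing ones)
    _present: frozenset[str] = frozenset({"execution", "selection", "description"})

    @classmethod
    def from_dict(cls, model_id: str, d: dict[str, Any]) -> "ModelMetadata":
        present = frozenset(k for k in ("execution", "selection", "description") if k in d)
        return cls(
            model_id=model_id,
            execution=ExecutionSection.from_dict(d.get("execution", {})),
            selection=SelectionSection.from_dict(d.get("selection", {})),
            description=DescriptionSection.from_dict(d.get("description", {})),
            _present=present,
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "execution": self.execution.to_dict(),
            "selection": self.selection.to_dict(),
            "description": self.description.to_dict(),
        }


# ---------------------------------------------------------------------------
# validation


def _finite_numbers(obj: Any, path: str, out: list[str]) -> None:
    if isinstance(obj, bool):
        return
    if isinstance(obj, (int, float)):
        if not math.isfinite(obj):
            out.append(f"selection.performance.{path}: value must be finite")
    elif isinstance(obj, dict):
        for k, v in obj.items():
            _finite_numbers(v, f"{path}.{k}" if path else str(k), out)


def validate_metadata(entry: ModelMetadata) -> list[str]:
    """Check one entry against the schema; return violation messages.

    An empty list means the entry is valid. Each message names the
    offending field and the rule it breaks.
    """
    v: list[str] = []
    if not is_valid_model_id(entry.model_id):
        v.append(
            f"model_id: {entry.model_id!r} does not match pattern "
            r"^\d{5}(_[A-Z0-9]+)+$"
        )
    for section in ("execution", "selection", "description"):
        if section not in entry._present:
            v.append(f"{section}: section missing")
    if not entry.execution.generate_method_name:
        v.append("execution.generate_method_name: must be non-empty")
    for dep in entry.execution.dependencies:
        if not isinstance(dep, str) or not dep.strip():
            v.append(f"execution.dependencies: invalid dependency entry {dep!r}")
    size = entry.execution.image_size
    if len(size) != 3 or any((not isinstance(s, int)) or s < 0 for s in size):
        v.append("execution.image_size: must be three non-negative integers (H, W, C)")
    _finite_numbers(entry.selection.performance, "", v)
    for kw in entry.selection.keywords:
        if not isinstance(kw, str) or not kw:
            v.append(f"selection.keywords: invalid keyword {kw!r}")
    if "description" in entry._present and not entry.description.title:
        v.append("description.title: must be non-empty")
    return v


# ---------------------------------------------------------------------------
# registry container


@dataclass
class Registry:
    """Ordered collection of model metadata entries keyed by model id."""

    entries: dict[str, ModelMetadata]
    source: str = ""
    schema_version: str = SCHEMA_VERSION

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ModelMetadata]:
        return iter(self.entries.values())

    def __contains__(self, model_id: str) -> bool:
        return model_id in self.entries

    @property
    def model_ids(self) -> list[str]:
        return list(self.entries)


def _edit_distance(a: str, b: str) -> int:
    # classic Levenshtein DP, small strings only
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def get_metadata(registry: Registry, model_id: str) -> ModelMetadata:
    """Constant-time lookup of one entry; unknown ids raise with suggestions.

    Ids are case-sensitive; the error lists the three registered ids
    closest to the request by edit distance.
    """
    try:
        return registry.entries[model_id]
    except KeyError:
        ranked = sorted(registry.entries, key=lambda m: _edit_distance(model_id, m))
        raise UnknownModelError(model_id, ranked[:3]) from None


# ---------------------------------------------------------------------------
# load / save


def _collect_duplicates(pairs: list[tuple[str, Any]], duplicates: list[str]) -> dict:
    d: dict[str, Any] = {}
    for k, val in pairs:
        if k in d:
            duplicates.append(k)
        d[k] = val  # last occurrence wins
    return d


def load_registry(source: str | Path, strict: bool = True) -> Registry:
    """Parse and validate a registry JSON file.

    Parameters
    ----------
    source
        Path to the registry file.
    strict
        When true (default), schema violations raise
        :class:`RegistryValidationError` listing every offending id and
        field; when false they are logged as warnings instead.
    """
    path = Path(source)
    text = path.read_text(encoding="utf-8")  # missing file -> OSError
    duplicates: list[str] = []
    try:
        raw = json.loads(text, object_pairs_hook=lambda p: _collect_duplicates(p, duplicates))
    except json.JSONDecodeError as e:
        raise RegistryParseError(
            f"malformed registry JSON in {path}: {e.msg} at byte offset {e.pos}",
            offset=e.pos,
        ) from e
    if not isinstance(raw, dict):
        raise RegistryParseError(f"registry {path} must be a JSON object keyed by model ids")
    for dup in duplicates:
        logger.warning("duplicate key %r in %s: keeping the last occurrence", dup, path)

    entries: dict[str, ModelMetadata] = {}
    violations: dict[str, list[str]] = {}
    for model_id, body in raw.items():
        entry = ModelMetadata.from_dict(model_id, body if isinstance(body, dict) else {})
        entries[model_id] = entry
        probs = validate_metadata(entry)
        if probs:
            violations[model_id] = probs
    if violations:
        if strict:
            raise RegistryValidationError(violations)
        for mid, probs in violations.items():
            logger.warning("registry entry %s: %s", mid, "; ".join(probs))
    return Registry(entries=entries, source=str(path))


def write_registry(registry: Registry, destination: str | Path) -> Path:
    """Serialize a registry back to JSON, preserving entry order."""
    path = Path(destination)
    payload = {mid: entry.to_dict() for mid, entry in registry.entries.items()}
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return path


def load_default_registry() -> Registry:
    """Load the bundled catalog of published models."""
    return load_registry(BUNDLED_ZOO)
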