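"""The ``Generators`` facade: one object composing every library capability.

Everything is lazy: constructing the facade touches no files, the
registry loads on its first use and is cached, and a model package is
resolved only when that model first generates. Typical use::

    from synthzoo import Generators

    generators = Generators(registry_source="fixture_zoo/registry.json")
    hits = generators.find_model(["patches", "mammography"], operator="AND")
    generators.generate(model_id=hits[0].model_id, num_samples=100,
                        save_images=True, output_path="out/", seed=7)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable, Iterator, Sequence

import numpy as np

from . import contributor as _contributor
from . import evaluation as _evaluation
from . import executor as _executor
from . import explorer as _explorer
from . import search as _search
from .config import FacadeConfig, load_config
from .errors import SynthZooError
from .registry import Registry, get_metadata, load_registry

logger = logging.getLogger(__name__)


@dataclass
class GenerationOutcome:
    """Result of a search-rank-generate composition."""

    model_id: str
    samples: list


class Generators:
    """Single access point to search, ranking, generation, exploration,
    evaluation, and contribution."""

    def __init__(
        self,
        registry_source: str | Path | None = None,
        cache_dir: str | Path | None = None,
        config: FacadeConfig | None = None,
        fetcher: Callable[[str], bytes] | None = None,
    ):
        overrides = {
            "registry_source": None if registry_source is None else str(registry_source),
            "cache_dir": None if cache_dir is None else str(cache_dir),
        }
        self.config = config or load_config(overrides)
        if config is not None:
            if registry_source is not None:
                self.config.registry_source = str(registry_source)
            if cache_dir is not None:
                self.config.cache_dir = str(cache_dir)
        self._fetcher = fetcher
        self._registry: Registry | None = None
        logging.getLogger("synthzoo").setLevel(self.config.log_level)

    # -- registry ----------------------------------------------------------

    @property
    def registry(self) -> Registry:
        """The registry, loaded on first access and cached."""
        if self._registry is None:
            self._registry = load_registry(self.config.registry_source)
            logger.info(
                "loaded registry %s (%d models)",
                self.config.registry_source, len(self._registry),
            )
        return self._registry

    def reload_registry(self) -> Registry:
        self._registry = None
        return self.registry

    def get_metadata(self, model_id: str):
        return get_metadata(self.registry, model_id)

    # -- search and ranking ------------------------------------------------

    def find_model(
        self, values: Sequence[str], operator: str = "AND"
    ) -> list[_search.MatchedEntry]:
        return _search.find_matching_models(self.registry, values, operator)

    def rank_models_by_performance(
        self,
        model_ids: Sequence[str] | None = None,
        metric: str = "FID",
        order: str | None = None,
    ) -> list[_search.RankedModel]:
        return _search.rank_models_by_performance(self.registry, model_ids, metric, order)

    def find_and_rank(
        self,
        values: Sequence[str],
        operator: str = "AND",
        metric: str = "FID",
        order: str | None = None,
    ) -> list[_search.RankedModel]:
        return _search.find_and_rank(self.registry, values, operator, metric, order)

    # -- generation --------------------------------------------------------

    def generate(
        self,
        model_id: str,
        num_samples: int = 10,
        save_images: bool = False,
        output_path: str | Path | None = None,
        install_dependencies: bool = False,
        batch_size: int | None = None,
        seed: int | None = None,
        **kwargs: Any,
    ):
        """Generate samples (returned, or written as PNGs with a manifest)."""
        request = _executor.GenerationRequest(
            model_id=model_id,
            num_samples=num_samples,
            save_images=save_images,
            output_path=output_path or (
                Path(self.config.samples_dir) / model_id if save_images else None
            ),
            install_dependencies=install_dependencies,
            batch_size=batch_size or self.config.default_batch_size,
            seed=seed,
            extra_args=kwargs,
        )
        return _executor.generate(
            request, self.registry, self.config.cache_dir, fetcher=self._fetcher
        )

    def get_generate_callable(self, model_id: str, **frozen: Any):
        return _executor.get_generate_callable(
            model_id, self.registry, self.config.cache_dir, frozen_defaults=frozen,
            fetcher=self._fetcher,
        )

    def get_as_iterator(
        self,
        model_id: str,
        batch_size: int | None = None,
        transform: Callable | None = None,
        length: int | None = None,
        seed: int | None = 0,
    ) -> Iterator[list]:
        """Batches of samples for training loops (framework-agnostic)."""
        return _executor.as_batch_iterator(
            model_id, self.registry, self.config.cache_dir,
            batch_size or self.config.default_batch_size, transform, length, seed,
        )

    # alias mirroring the dataset-adapter naming
    get_as_dataset = get_as_iterator

    def find_models_rank_and_generate(
        self,
        values: Sequence[str],
        metric: str = "FID",
        operator: str = "AND",
        order: str | None = None,
        num_samples: int = 10,
        save_images: bool = False,
        output_path: str | Path | None = None,
        seed: int | None = None,
        **kwargs: Any,
    ) -> GenerationOutcome:
        """Search, rank the matches, and generate with the best-ranked model."""
        ranked = self.find_and_rank(values, operator, metric, order)
        if not ranked:
            raise SynthZooError(
                f"no model matches query {list(values)!r} under {operator}"
            )
        chosen = ranked[0].model_id
        logger.info("query %r -> %d match(es); generating with %s",
                    list(values), len(ranked), chosen)
        samples = self.generate(
            chosen, num_samples=num_samples, save_images=save_images,
            output_path=output_path, seed=seed, **kwargs,
        )
        return GenerationOutcome(model_id=chosen, samples=samples)

    # -- exploration -------------------------------------------------------

    def visualize(
        self, model_id: str, slider_grouper: int = 10, seed: int = 0
    ) -> _explorer.ExplorerState:
        """Headless explorer state; a GUI may bind to it, none is required."""
        return _explorer.init_state(model_id, self.registry, slider_grouper, seed)

    def render(self, state: _explorer.ExplorerState) -> _executor.SampleItem:
        return _explorer.render(state, self.registry, self.config.cache_dir)

    # -- evaluation --------------------------------------------------------

    def evaluate(
        self,
        model_id: str,
        real_set: Sequence[np.ndarray] | np.ndarray,
        n_syn: int = 200,
        extractor: _evaluation.FeatureExtractor | None = None,
        normalize: str | bool | None = None,
        seed: int = 0,
    ) -> _evaluation.FidReport:
        """FIDrr / FIDrs / rFID report for one model against a real set."""
        if extractor is None:
            from .fixtures import toy_feature_extractor
            extractor = toy_feature_extractor()
        return _evaluation.evaluate_model(
            model_id, self.registry, real_set, n_syn, extractor, normalize, seed,
            cache_dir=self.config.cache_dir,
        )

    # -- contribution ------------------------------------------------------

    def contribute(
        self,
        model_id: str,
        init_py_path: str | Path,
        generate_method_name: str = "generate",
        model_weights_name: str = "",
        model_weights_extension: str = "",
        dependencies: Sequence[str] = (),
        image_size: tuple[int, int, int] = (64, 64, 1),
        latent_dim: int | None = None,
        performance: dict | None = None,
        publisher: _contributor.Publisher | None = None,
        strict: bool = False,
        **extra_metadata: Any,
    ) -> _contributor.ContributionResult:
        """Validate, test, register, and package a new model end to end.

        On success the facade's registry is reloaded so the contributed
        model is immediately generable.
        """
        request = _contributor.ContributionRequest(
            model_id=model_id,
            init_script_path=init_py_path,
            generate_method_name=generate_method_name,
            weights_name=model_weights_name,
            weights_extension=model_weights_extension,
            dependencies=list(dependencies),
            image_size=image_size,
            latent_dim=latent_dim,
            extra_metadata=extra_metadata,
        )
        violations = _contributor.validate_contribution(request)
        if violations:
            raise SynthZooError("contribution invalid:\n" + "\n".join(violations))
        entry = _contributor.build_metadata_entry(request, measured=performance)
        result = _contributor.register_and_package(
            entry, self.config.registry_source, Path(init_py_path).parent,
            publisher=publisher, cache_dir=self.config.cache_dir, strict=strict,
        )
        self.reload_registry()
        return result

    def test_model(self, model_id: str) -> tuple[bool, list[str]]:
        entry = self.get_metadata(model_id)
        return _contributor.test_model(entry, self.config.cache_dir)
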