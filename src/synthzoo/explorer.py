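"""Headless state machine for latent-space exploration.

Noise-to-image generators take a latent vector z whose dimension d is
often large, so individual dimensions make poor interactive controls.
Dimensions are therefore grouped: with group size n, slider i governs
dims ``[i*n, min((i+1)*n, d))``, giving ceil(d/n) sliders. The state is
immutable — every operation returns a new state — so an optional GUI can
bind to it while all the logic stays testable without a display.

Operations mirror the interactive controls: move a slider (set every
dimension of its group), reseed (draw a fresh z), reset (revert edits to
the last seeded z), and render (generate the image, and mask when the
model emits one, for the current z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import executor as _executor
from .errors import UnsupportedModelError
from .registry import Registry, get_metadata


@dataclass(frozen=True)
class ExplorerState:
    """Immutable snapshot of one exploration session."""

    model_id: str
    z: tuple[float, ...]
    group_size: int
    sliders: tuple[float, ...]
    last_seeded_z: tuple[float, ...]
    condition: int | None
    seed: int

    @property
    def latent_dim(self) -> int:
        return len(self.z)

    @property
    def n_sliders(self) -> int:
        return len(self.sliders)

    def group_dims(self, index: int) -> range:
        d, n = len(self.z), self.group_size
        return range(index * n, min((index + 1) * n, d))


def _group_means(z: np.ndarray, group_size: int) -> tuple[float, ...]:
    d = z.size
    count = math.ceil(d / group_size)
    return tuple(
        float(z[i * group_size: min((i + 1) * group_size, d)].mean())
        for i in range(count)
    )


def init_state(
    model_id: str,
    registry: Registry,
    group_size: int = 10,
    seed: int = 0,
) -> ExplorerState:
    """Start a session: draw z ~ N(0, I) with ``seed`` and group the dims.

    Slider values initialize to the mean of their group's dimensions.
    Models without a declared latent dimension (pure image-to-image
    translators) cannot be explored this way.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    metadata = get_metadata(registry, model_id)
    d = metadata.execution.latent_dim
    if not d:
        raise UnsupportedModelError(
            f"model {model_id} declares no latent input; latent exploration "
            "is only defined for noise-to-image models"
        )
    z = np.random.default_rng(seed).standard_normal(d)
    return ExplorerState(
        model_id=model_id,
        z=tuple(float(v) for v in z),
        group_size=group_size,
        sliders=_group_means(z, group_size),
        last_seeded_z=tuple(float(v) for v in z),
        condition=None,
        seed=seed,
    )


def set_slider(state: ExplorerState, index: int, value: float) -> ExplorerState:
    """Set every dimension of slider ``index``'s group to ``value``."""
    if not (0 <= index < state.n_sliders):
        raise ValueError(
            f"slider index {index} out of range [0, {state.n_sliders})"
        )
    z = np.array(state.z)
    z[list(state.group_dims(index))] = value
    sliders = list(state.sliders)
    sliders[index] = float(value)
    return replace(state, z=tuple(float(v) for v in z), sliders=tuple(sliders))


def set_condition(state: ExplorerState, condition: int | None) -> ExplorerState:
    """Change the class-conditional label fed to the model."""
    return replace(state, condition=condition)


def reseed(state: ExplorerState, new_seed: int) -> ExplorerState:
    """Draw a fresh z from ``new_seed``; it becomes the new reset target."""
    z = np.random.default_rng(new_seed).standard_normal(state.latent_dim)
    return replace(
        state,
        z=tuple(float(v) for v in z),
        last_seeded_z=tuple(float(v) for v in z),
        sliders=_group_means(z, state.group_size),
        seed=new_seed,
    )


def reset(state: ExplorerState) -> ExplorerState:
    """Revert slider edits: restore the last seeded z (seed unchanged)."""
    z = np.array(state.last_seeded_z)
    return replace(
        state,
        z=tuple(state.last_seeded_z),
        sliders=_group_means(z, state.group_size),
    )


def render(
    state: ExplorerState,
    registry: Registry,
    cache_dir: str | Path | None = None,
) -> _executor.SampleItem:
    """Generate the one sample the current state describes.

    The model receives ``input_latent_vector = z`` (and the condition if
    set), so the output is a deterministic function of the state.
    """
    extra: dict = {"input_latent_vector": np.array(state.z)}
    if state.condition is not None:
        extra["condition"] = state.condition
    samples = _executor.generate(
        _executor.GenerationRequest(
            model_id=state.model_id, num_samples=1, seed=state.seed, extra_args=extra,
        ),
        registry, cache_dir,
    )
    return samples[0]
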