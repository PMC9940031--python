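"""Offline test assets: procedural model packages, image sets, toy extractor.

Real generative models in the zoo are large hosted networks; everything
here is a closed-form stand-in that exercises the same interfaces.
Four package templates cover the supported generation scenarios:

``noise_to_image``
    seeded Gaussian-blob "mass" patches, 64x64 grayscale, latent d=16;
``image_plus_mask``
    ellipse "polyp" patches with a binary segmentation mask, latent d=8;
``class_conditional``
    striped vs. checkerboard texture patches with labels {0, 1};
``image_to_image``
    an intensity-inverting translator (no latent input).

All templates honour the executor's determinism contract: sample ``i``
derives its randomness from ``(seed, sample_offset + i)``, and a given
latent vector ``z`` maps to one image, so distinct ``z`` give distinct
images (needed by the latent explorer). ``synth_image_set`` draws from
the same blob distribution as the noise-to-image package, optionally
with an intensity shift, so real-vs-synthetic FID experiments have a
known ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .evaluation import FeatureExtractor
from .registry import load_registry

__all__ = [
    "build_fixture_zoo", "synth_image_set", "toy_feature_extractor",
    "render_blob", "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("noise_to_image", "image_plus_mask", "class_conditional", "image_to_image")

_MODULUS = 2**31

# Shared renderer: embedded verbatim in the noise-to-image package template
# and exec'd below, so package output and synth_image_set stay one
# distribution by construction.
_BLOB_SOURCE = '''
def _blob_image(z, size=64, intensity_shift=0.0):
    z = np.asarray(z, dtype=float)
    zp = np.zeros(16)
    zp[:min(16, z.size)] = z[:16]
    yy, xx = np.mgrid[0:size, 0:size]
    cy = size / 2.0 + 0.18 * size * np.tanh(zp[0])
    cx = size / 2.0 + 0.18 * size * np.tanh(zp[1])
    sigma = 0.11 * size * (1.0 + 0.35 * np.tanh(zp[2]))
    amp = 150.0 + 40.0 * np.tanh(zp[3])
    img = amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2))
    img = img + 20.0 + 8.0 * np.tanh(zp[4])
    for k in range(5, 16):
        f = (k - 3) // 2
        if k % 2:
            wave = np.sin(2.0 * np.pi * f * xx / size)
        else:
            wave = np.cos(2.0 * np.pi * f * yy / size)
        img = img + 2.5 * np.tanh(zp[k]) * wave
    img = img + intensity_shift
    return np.clip(img, 0, 255).astype(np.uint8)[:, :, None]
'''

_ns: dict = {"np": np}
exec(_BLOB_SOURCE, _ns)
render_blob = _ns["_blob_image"]


_COMMON_HEADER = '''import json

import numpy as np


def _rng(seed, index):
    seed = 0 if seed is None else int(seed) % (2**31)
    return np.random.default_rng([seed, int(index)])


def _params(model_file, defaults):
    if not model_file:
        return dict(defaults)
    with open(model_file) as fh:
        loaded = json.load(fh)
    merged = dict(defaults)
    merged.update(loaded)
    return merged
'''

_BLOB_TEMPLATE = ('"""Procedural Gaussian-blob generator: grayscale mass-like patches."""\n'
                  + _COMMON_HEADER + "\n" + _BLOB_SOURCE + '''

def generate(model_file=None, num_samples=1, save_images=False, output_path=None,
             seed=0, sample_offset=0, input_latent_vector=None,
             intensity_shift=0.0, **kwargs):
    params = _params(model_file, {"latent_dim": 16, "size": 64})
    d = int(params["latent_dim"])
    size = int(params["size"])
    out = []
    for i in range(int(num_samples)):
        if input_latent_vector is not None:
            z = np.asarray(input_latent_vector, dtype=float)
        else:
            z = _rng(seed, sample_offset + i).standard_normal(d)
        out.append({"image": _blob_image(z, size=size,
                                         intensity_shift=float(intensity_shift))})
    return out
''')

_POLYP_TEMPLATE = ('"""Procedural ellipse generator: polyp-like patches with binary masks."""\n'
                   + _COMMON_HEADER + '''

def _ellipse_pair(z, size=64):
    z = np.asarray(z, dtype=float)
    zp = np.zeros(8)
    zp[:min(8, z.size)] = z[:8]
    yy, xx = np.mgrid[0:size, 0:size]
    cy = size / 2.0 + 0.15 * size * np.tanh(zp[0])
    cx = size / 2.0 + 0.15 * size * np.tanh(zp[1])
    a = 0.14 * size * (1.0 + 0.3 * np.tanh(zp[2]))
    b = 0.10 * size * (1.0 + 0.3 * np.tanh(zp[3]))
    theta = 0.6 * np.tanh(zp[4])
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    fg = 160.0 + 40.0 * np.tanh(zp[5])
    bg = 30.0 + 10.0 * np.tanh(zp[6])
    img = np.full((size, size), bg)
    img = img + 3.0 * np.tanh(zp[7]) * np.sin(2.0 * np.pi * 3.0 * xx / size)
    img[inside] = fg
    image = np.clip(img, 0, 255).astype(np.uint8)[:, :, None]
    mask = np.where(inside, 255, 0).astype(np.uint8)
    return image, mask


def generate(model_file=None, num_samples=1, save_images=False, output_path=None,
             seed=0, sample_offset=0, input_latent_vector=None, **kwargs):
    params = _params(model_file, {"latent_dim": 8, "size": 64})
    d = int(params["latent_dim"])
    size = int(params["size"])
    out = []
    for i in range(int(num_samples)):
        if input_latent_vector is not None:
            z = np.asarray(input_latent_vector, dtype=float)
        else:
            z = _rng(seed, sample_offset + i).standard_normal(d)
        image, mask = _ellipse_pair(z, size=size)
        out.append({"image": image, "mask": mask})
    return out
''')

_TEXTURE_TEMPLATE = ('"""Procedural class-conditional texture generator (labels 0/1)."""\n'
                     + _COMMON_HEADER + '''

def _texture(z, label, size=64):
    z = np.asarray(z, dtype=float)
    zp = np.zeros(16)
    zp[:min(16, z.size)] = z[:16]
    yy, xx = np.mgrid[0:size, 0:size]
    freq = 4.0 + 2.0 * np.tanh(zp[0])
    amp = 80.0 + 20.0 * np.tanh(zp[1])
    base = 100.0 + 20.0 * np.tanh(zp[2])
    if int(label) == 0:
        pattern = np.sin(2.0 * np.pi * freq * yy / size)
    else:
        pattern = np.sin(2.0 * np.pi * freq * yy / size) * np.sin(2.0 * np.pi * freq * xx / size)
    img = base + amp * pattern + 4.0 * np.tanh(zp[3]) * np.cos(2.0 * np.pi * xx / size)
    return np.clip(img, 0, 255).astype(np.uint8)[:, :, None]


def generate(model_file=None, num_samples=1, save_images=False, output_path=None,
             seed=0, sample_offset=0, input_latent_vector=None, condition=None,
             **kwargs):
    params = _params(model_file, {"latent_dim": 16, "size": 64})
    d = int(params["latent_dim"])
    size = int(params["size"])
    out = []
    for i in range(int(num_samples)):
        rng = _rng(seed, sample_offset + i)
        label = int(rng.integers(0, 2)) if condition is None else int(condition)
        if input_latent_vector is not None:
            z = np.asarray(input_latent_vector, dtype=float)
        else:
            z = rng.standard_normal(d)
        out.append({"image": _texture(z, label, size=size), "label": label})
    return out
''')

_INVERT_TEMPLATE = ('"""Intensity-inverting image-to-image translator."""\n'
                    + _COMMON_HEADER + '''

def _default_input(index, size=64):
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy + xx + 7 * int(index)) % 256).astype(np.uint8)[:, :, None]


def generate(model_file=None, num_samples=1, save_images=False, output_path=None,
             seed=0, sample_offset=0, input_images=None, **kwargs):
    params = _params(model_file, {"size": 64})
    size = int(params["size"])
    out = []
    for i in range(int(num_samples)):
        if input_images is not None:
            src = np.asarray(input_images[(sample_offset + i) % len(input_images)])
            if src.ndim == 2:
                src = src[:, :, None]
        else:
            src = _default_input(sample_offset + i, size=size)
        out.append({"image": (255 - src.astype(np.int64)).astype(np.uint8)})
    return out
''')


_ZOO_SPEC = [
    # (model_id, dirname, template, weights params, latent_dim, keywords, performance, title)
    (
        "00001_BLOB_MASS", "blob_mass", _BLOB_TEMPLATE,
        {"latent_dim": 16, "size": 64}, 16,
        ["mammography", "mass", "patches"],
        {"FID": 12.5, "FIDrr": 6.0, "downstream": {"dice": 0.83}},
        "Gaussian-blob mass patches",
    ),
    (
        "00002_POLYP_MASK", "polyp_mask", _POLYP_TEMPLATE,
        {"latent_dim": 8, "size": 64}, 8,
        ["endoscopy", "polyp", "mask"],
        {"FID": 18.75, "FIDrr": 7.5},
        "Ellipse polyp patches with masks",
    ),
    (
        "00003_TEXTURE_CLASS", "texture_class", _TEXTURE_TEMPLATE,
        {"latent_dim": 16, "size": 64}, 16,
        ["mammography", "patches", "conditional", "classification"],
        {"FID": 31.0},
        "Class-conditional texture patches",
    ),
    (
        "00004_INVERT_I2I", "invert_i2i", _INVERT_TEMPLATE,
        {"size": 64}, None,
        ["mammography", "translation", "image-to-image"],
        {"SSIM": 0.91},  # deliberately no FID: exercises missing-metric ranking
        "Intensity-inverting translator",
    ),
]


def build_fixture_zoo(target_dir: str | Path, seed: int = 0) -> tuple[Path, list[Path]]:
    """Write the fixture model packages and a registry referencing them.

    Returns ``(registry_path, package_dirs)``. Content is deterministic:
    the same seed produces byte-identical packages. A fifth registry
    entry reuses the blob package with a +64 intensity shift, giving a
    model with a known distribution mismatch for FID experiments.
    """
    target = Path(target_dir)
    target.mkdir(parents=True, exist_ok=True)
    pkg_root = target / "packages"
    pkg_root.mkdir(exist_ok=True)

    entries: dict[str, dict] = {}
    package_dirs: list[Path] = []
    for model_id, dirname, template, params, latent_dim, keywords, perf, title in _ZOO_SPEC:
        pkg_dir = pkg_root / dirname
        pkg_dir.mkdir(exist_ok=True)
        (pkg_dir / "__init__.py").write_text(template, encoding="utf-8")
        weights = dict(params)
        weights["fixture_seed"] = int(seed)
        (pkg_dir / "weights.json").write_text(json.dumps(weights, indent=2) + "\n")
        (pkg_dir / "LICENSE").write_text("MIT License (fixture package)\n")
        (pkg_dir / "requirements.txt").write_text("numpy\n")
        package_dirs.append(pkg_dir)

        execution = {
            "package_location": str(pkg_dir),
            "package_name": dirname,
            "weights_name": "weights",
            "weights_extension": ".json",
            "dependencies": ["numpy"],
            "generate_method_name": "generate",
            "generate_args": {},
            "image_size": [64, 64, 1],
        }
        if latent_dim is not None:
            execution["latent_dim"] = latent_dim
        entries[model_id] = {
            "execution": execution,
            "selection": {"performance": perf, "keywords": keywords},
            "description": {
                "title": title,
                "modality": keywords[0],
                "output_type": "image+mask" if "mask" in keywords else "image",
                "training_dataset": "procedural",
                "license": "MIT",
                "date": "2026-01-01",
                "publication": "",
            },
        }

    # shifted variant of the blob model: same package, +64 intensity offset
    shifted = json.loads(json.dumps(entries["00001_BLOB_MASS"]))
    shifted["execution"]["generate_args"] = {"intensity_shift": 64.0}
    shifted["selection"] = {
        "performance": {"FID": 55.0, "FIDrr": 6.0},
        "keywords": ["mammography", "mass", "patches", "shifted"],
    }
    shifted["description"]["title"] = "Gaussian-blob mass patches, intensity-shifted"
    entries["00005_BLOB_MASS_SHIFT"] = shifted

    registry_path = target / "registry.json"
    registry_path.write_text(json.dumps(entries, indent=2) + "\n", encoding="utf-8")
    load_registry(registry_path)  # sanity: the zoo must validate
    return registry_path, package_dirs


def synth_image_set(
    n: int,
    size: int = 64,
    seed: int = 0,
    shift: float = 0.0,
    class_mix: Sequence[float] | None = None,
) -> np.ndarray:
    """Draw n images from the fixture blob (or texture) distribution.

    With ``class_mix`` given, samples come from the class-conditional
    texture distribution with those label proportions instead. ``shift``
    adds a constant intensity offset before the 8-bit clip, emulating a
    miscalibrated generator. Deterministic per seed; sample ``i`` is keyed
    by ``(seed, i)`` exactly like the fixture packages.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    images = []
    for i in range(n):
        rng = np.random.default_rng([int(seed) % _MODULUS, i])
        if class_mix is not None:
            mix = np.asarray(class_mix, dtype=float)
            label = int(rng.choice(len(mix), p=mix / mix.sum()))
            z = rng.standard_normal(16)
            img = _texture_render(z, label, size=size, shift=shift)
        else:
            z = rng.standard_normal(16)
            img = render_blob(z, size=size, intensity_shift=shift)
        images.append(img)
    return np.stack(images)


def _texture_render(z, label, size=64, shift=0.0):
    zp = np.zeros(16)
    zp[: min(16, np.size(z))] = np.asarray(z)[:16]
    yy, xx = np.mgrid[0:size, 0:size]
    freq = 4.0 + 2.0 * np.tanh(zp[0])
    amp = 80.0 + 20.0 * np.tanh(zp[1])
    base = 100.0 + 20.0 * np.tanh(zp[2])
    if int(label) == 0:
        pattern = np.sin(2.0 * np.pi * freq * yy / size)
    else:
        pattern = np.sin(2.0 * np.pi * freq * yy / size) * np.sin(2.0 * np.pi * freq * xx / size)
    img = base + amp * pattern + 4.0 * np.tanh(zp[3]) * np.cos(2.0 * np.pi * xx / size)
    return np.clip(img + shift, 0, 255).astype(np.uint8)[:, :, None]


def toy_feature_extractor(seed: int = 0, d: int = 64) -> FeatureExtractor:
    """Deterministic random-projection extractor for metric tests.

    Images are average-pooled on an 8x8 grid and the 64 pooled values are
    mapped through a fixed seeded Gaussian projection to ``d``
    dimensions. Registered under id ``toy-rp-{seed}-{d}``.
    """
    rng = np.random.default_rng(seed)
    projection = rng.standard_normal((64, d)) / np.sqrt(64.0)

    def extract(images: np.ndarray) -> np.ndarray:
        arr = np.asarray(images, dtype=float)
        n, h, w, _ = arr.shape
        gray = arr.mean(axis=3)
        pooled = gray.reshape(n, 8, h // 8, 8, w // 8).mean(axis=(2, 4))
        return pooled.reshape(n, 64) @ projection

    return FeatureExtractor(
        id=f"toy-rp-{seed}-{d}", expected_input=(64, 64, 1), fn=extract,
    )
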