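"""Explore a generator's latent space headlessly: sliders, reseed, reset.

A noise-to-image model maps a latent vector z (here d=16) to an image.
Dimensions are grouped into sliders (group size 4 -> 4 sliders); moving a
slider sets every dimension of its group, reseed draws a fresh z, and
reset reverts edits to the last seeded z.
"""

import tempfile
from pathlib import Path

import numpy as np

from synthzoo import Generators
from synthzoo.explorer import reset, set_slider

workdir = Path(tempfile.mkdtemp(prefix="synthzoo_example_"))
from synthzoo.fixtures import build_fixture_zoo

registry_path, _ = build_fixture_zoo(workdir / "zoo", seed=0)
generators = Generators(registry_source=registry_path, cache_dir=workdir / "cache")

state = generators.visualize("00001_BLOB_MASS", slider_grouper=4, seed=6)
print(f"latent dim {state.latent_dim}, {state.n_sliders} sliders of group size "
      f"{state.group_size}")
print("initial slider values (group means of z):",
      ", ".join(f"{v:+.3f}" for v in state.sliders))

base = generators.render(state).image
edited = set_slider(state, 0, 2.0)   # push the blob off-center
moved = generators.render(edited).image
print(f"\nmoving slider 0 changed {int((base != moved).sum())} of {base.size} pixels")

restored = generators.render(reset(edited)).image
print("after reset the render matches the original:",
      np.array_equal(base, restored))
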