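"""synthzoo: a metadata-driven zoo of generative models for medical images.

Search and rank registered models, run them to generate synthetic
samples, explore their latent space, contribute new models, and evaluate
synthetic image sets with the Fréchet inception distance (FID), its
real-real lower bound FIDrr, and the FID ratio rFID.

Importing the package performs no I/O; the registry and model packages
load lazily on first use (see :class:`synthzoo.facade.Generators`).
"""

from importlib import import_module as _import_module

__version__ = "0.1.0"

__all__ = [
    "Generators",
    "FacadeConfig",
    "registry",
    "search",
    "executor",
    "evaluation",
    "contributor",
    "explorer",
    "fixtures",
    "errors",
]

_LAZY = {
    "Generators": ("synthzoo.facade", "Generators"),
    "FacadeConfig": ("synthzoo.config", "FacadeConfig"),
}


def __getattr__(name: str):
    if name in _LAZY:
        module, attr = _LAZY[name]
        return getattr(_import_module(module), attr)
    if name in __all__:
        return _import_module(f"synthzoo.{name}")
    raise AttributeError(f"module 'synthzoo' has no attribute {name!r}")
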