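"""Exception hierarchy for synthzoo."""


class SynthZooError(Exception):
    """Base class for all synthzoo errors."""


class RegistryError(SynthZooError):
    """Problems loading, parsing, or validating the model registry."""


class RegistryParseError(RegistryError):
    """Malformed registry JSON; carries the byte offset of the failure."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class RegistryValidationError(RegistryError):
    """One or more registry entries violate the metadata schema."""

    def __init__(self, violations: dict[str, list[str]]):
        self.violations = violations
        lines = [f"{mid}: {'; '.join(v)}" for mid, v in violations.items()]
        super().__init__("registry validation failed:\n" + "\n".join(lines))


class UnknownModelError(SynthZooError, KeyError):
    """Requested model id is not in the registry; suggests close ids."""

    def __init__(self, model_id: str, suggestions: list[str]):
        self.model_id = model_id
        self.suggestions = suggestions
        hint = f" (closest ids: {', '.join(suggestions)})" if suggestions else ""
        SynthZooError.__init__(self, f"unknown model id {model_id!r}{hint}")

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


class PackageResolutionError(SynthZooError):
    """Model package could not be fetched, unpacked, or laid out."""


class DependencyError(SynthZooError):
    """A model dependency could not be installed."""


class ModelExecutionError(SynthZooError):
    """The model's generate callable raised; carries model id and batch index."""

    def __init__(self, model_id: str, batch_index: int, cause: BaseException):
        self.model_id = model_id
        self.batch_index = batch_index
        super().__init__(
            f"model {model_id} failed in batch {batch_index}: {cause!r}"
        )


class UnsupportedModelError(SynthZooError):
    """Operation requires a capability the model does not declare (e.g. a latent input)."""


class ContributionError(SynthZooError):
    """Contribution workflow failure (validation, test, or registration)."""


class ConflictError(ContributionError):
    """Attempt to register a model id that already exists."""


class NumericalError(SynthZooError):
    """A numerical routine (e.g. the covariance matrix square root) failed."""
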