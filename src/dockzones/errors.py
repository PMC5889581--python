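"""Exception hierarchy shared by all stages."""


class DockzonesError(Exception):
    """Base class for all package errors."""


class ValidationError(DockzonesError):
    """Invalid arguments or inconsistent inputs."""


class ChainSelectionError(ValidationError):
    """A requested chain is absent from the structure."""

    def __init__(self, chain_id: str, available: tuple[str, ...] = ()):
        self.chain_id = chain_id
        self.available = tuple(available)
        msg = f"chain {chain_id!r} not found"
        if available:
            msg += f" (available: {', '.join(sorted(self.available))})"
        super().__init__(msg)


class EmptyEnsembleError(ValidationError):
    """No configuration could be resolved from the inputs."""


class DegenerateInputError(DockzonesError):
    """Geometric input without enough independent information."""


class GenerationError(DockzonesError):
    """Synthetic fixture specification cannot be realized."""


class AlignmentError(DockzonesError):
    """Superposition failed for a named configuration."""

    def __init__(self, config_id: str, reason: str):
        self.config_id = config_id
        super().__init__(f"cannot align configuration {config_id!r}: {reason}")


class LayoutError(DockzonesError):
    """A view layout cannot be constructed."""


class ExportError(DockzonesError):
    """An export target cannot be produced."""


class StageError(DockzonesError):
    """Pipeline stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
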