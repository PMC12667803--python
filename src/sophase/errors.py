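"""Exception hierarchy for the pipeline."""


class SophaseError(Exception):
    """Base class for all package errors."""


class ConfigError(SophaseError):
    """Invalid generator or run configuration."""


class ChannelMissingError(SophaseError):
    """A required channel is absent from a recording."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing channels: {', '.join(self.missing)}")


class GenerationError(SophaseError):
    """Synthetic-data generation could not satisfy its constraints."""


class ResamplingDirectionError(SophaseError):
    """Recording sampled below the analysis rate; upsampling is refused."""


class DegenerateSignalError(SophaseError):
    """Zero-variance usable signal; z-scores undefined."""


class UnidentifiableSlopeError(SophaseError):
    """All positions identical; circular-linear slope not identifiable."""


class InsufficientDataError(SophaseError):
    """Too few samples or surviving points for the requested fit."""


class UndefinedStatisticError(SophaseError):
    """Circular statistics requested on an empty sample."""


class CollinearityError(SophaseError):
    """Rank-deficient regression design."""
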