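"""Exception hierarchy for latentfed.

Every contract violation raises a subclass of :class:`LatentFedError`, so
callers can catch one base class at protocol boundaries.
"""


class LatentFedError(Exception):
    """Base class for all latentfed errors."""


class SchemaError(LatentFedError):
    """A dataset, file or model does not match the declared schema."""


class FormatError(LatentFedError):
    """A delimited text file is malformed (e.g. duplicate header)."""


class PlanError(LatentFedError):
    """A vertical plan omits, duplicates or invents feature columns."""


class DegenerateLabelsError(LatentFedError):
    """An operation requiring both classes saw only one."""


class StratificationError(LatentFedError):
    """A class has too few rows for a stratified split."""


class ConfigurationError(LatentFedError):
    """An unknown rule name or invalid hyperparameter configuration."""


class OvercompletenessError(ConfigurationError):
    """The code layer is narrower than the post-embedding input (m < n)."""


class DivergenceError(LatentFedError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


class EncodeError(SchemaError):
    """Input columns do not match the columns a model was trained on."""


class AlignmentError(LatentFedError):
    """Row identifiers cannot be aligned across sites."""


class InputError(LatentFedError):
    """Mismatched vector lengths or otherwise inconsistent inputs."""
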