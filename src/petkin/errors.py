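"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError -> 3.
"""


class PetkinError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PetkinError):
    """Invalid or inconsistent run configuration (bad thresholds, missing params)."""


class DataError(PetkinError):
    """Problem with input data files or their contents."""


class SchemaError(DataError):
    """A delimited table is missing required columns."""


class ParseError(DataError):
    """A table cell could not be interpreted (non-numeric score, unknown sex code)."""


class ScheduleMismatchError(DataError):
    """Frame schedule length disagrees with the image's 4th dimension."""


class MissingMetadataError(DataError):
    """A required sidecar (frame schedule, label map) was not found."""


class ContractError(PetkinError):
    """A caller violated a documented precondition."""


class CoverageError(ContractError):
    """An input curve does not span the requested time support."""


class InsufficientDataError(ContractError):
    """Too few samples/frames for the requested fit."""


class FitFailureError(PetkinError):
    """Nonlinear fit failed to converge after multi-start."""
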