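"""Exception hierarchy for sheartex."""


class SheartexError(Exception):
    """Base class for all sheartex errors."""


class SizingError(SheartexError, ValueError):
    """Image too small for the requested decomposition."""


class FormatError(SheartexError, ValueError):
    """Unsupported raster layout or channel count."""


class DimensionError(SheartexError, ValueError):
    """Array shape does not match the expected contract."""


class CompletenessError(SheartexError, ValueError):
    """A coefficient stack is missing bands required for reconstruction."""


class DataError(SheartexError, ValueError):
    """Input values violate a descriptor precondition (non-finite, too small)."""


class ContractError(SheartexError, ValueError):
    """An intermediate object violates its documented contract."""


class AssemblyError(SheartexError, KeyError):
    """A fusion recipe references a feature block that is not available."""


class ParameterError(SheartexError, ValueError):
    """A configuration value is outside its valid range."""


class LoaderError(SheartexError, ValueError):
    """A dataset folder or file could not be read."""
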