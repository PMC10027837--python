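"""Exception hierarchy for the ROK engine."""


class RokError(Exception):
    """Base class for all engine errors."""


class InvalidParameterError(RokError, ValueError):
    """A parameter value violates its documented range or type."""


class UnknownParameterError(InvalidParameterError):
    """A configuration document contains a key the engine does not define."""


class ContractViolationError(RokError, RuntimeError):
    """An operation was called outside its stated precondition."""


class MissingAssetError(RokError, FileNotFoundError):
    """A sprite or background image reference could not be resolved."""


class InvalidDataError(RokError, ValueError):
    """A log or record is malformed or inconsistent with its scene."""
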