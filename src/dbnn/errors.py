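"""Exception hierarchy shared across the package."""


class DBNNError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DBNNError, ValueError):
    """A configuration field or operation argument is out of its domain."""


class GeometryError(DBNNError, ValueError):
    """A box, lesion or crop does not fit inside its image."""


class ContractError(DBNNError, ValueError):
    """Mismatched shapes/lengths between arguments that must correspond."""


class NumericError(DBNNError, ArithmeticError):
    """Non-finite values appeared where finite ones are required."""


class ReconstructionError(DBNNError, ValueError):
    """A printed metric panel admits zero or several integer confusion
    matrices; carries the candidate list for inspection."""

    def __init__(self, message: str, candidates=()):
        super().__init__(message)
        self.candidates = list(candidates)
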