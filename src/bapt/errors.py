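"""Exception hierarchy shared across the package."""


class BaptError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BaptError):
    """A config file, table row or domain object violates its invariants."""


class InconsistencyError(BaptError):
    """A judgement (or judgement set) contradicts earlier preferences.

    Carries the offending preference chain when one could be reconstructed.
    """

    def __init__(self, message, chain=None):
        super().__init__(message)
        self.chain = list(chain) if chain is not None else []
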