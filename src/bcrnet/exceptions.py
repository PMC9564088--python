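"""Exception types shared across the package."""


class BcrnetError(Exception):
    """Base class for all package errors."""


class RepertoireFormatError(BcrnetError):
    """A clonotype/cohort/signature table does not match its declared dialect."""


class EmptyRepertoireError(BcrnetError):
    """An operation received a repertoire with no valid clonotypes."""


class ValidationError(BcrnetError):
    """An input value violates a documented invariant."""


class DegenerateDataError(BcrnetError):
    """A statistical routine received data it cannot meaningfully analyze
    (e.g. zero-variance groups, single-class labels, zero healthy mean)."""
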