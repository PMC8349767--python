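"""Exception hierarchy shared across the pipeline."""


class NucperiodError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NucperiodError):
    """An input file violates its declared format."""


class ValidationError(NucperiodError):
    """Input content is well-formed but inconsistent (e.g. wrong genome build)."""


class UnsortedInputError(NucperiodError):
    """A coordinate-sorted precondition was violated."""


class InsufficientMutationsError(NucperiodError):
    """Fewer dyad-mapped mutations than the minimum needed for a periodogram."""

    def __init__(self, n_mapped: int, minimum: int):
        self.n_mapped = n_mapped
        self.minimum = minimum
        super().__init__(
            f"only {n_mapped} mutations map within nucleosome dyad windows; "
            f"at least {minimum} are required for a meaningful periodogram"
        )
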