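"""Typed exceptions used across the package."""


class KmerwalkError(Exception):
    """Base class for all kmerwalk errors."""


class ParameterError(KmerwalkError, ValueError):
    """Invalid design parameters (e.g. k > L, bad window)."""


class AlphabetError(ParameterError):
    """Symbol outside the allowed alphabet, or an ill-formed alphabet."""


class ContractError(KmerwalkError):
    """A precondition of a strategy was violated (e.g. even k where an
    odd-k argument is required, or a four-letter library passed to the
    three-letter reverse-complement filter)."""


class InfeasibleDesignError(KmerwalkError):
    """No parameter choice can satisfy the request (e.g. desired library
    size exceeds the k = L maximum)."""


class FormatError(KmerwalkError):
    """Malformed input file (FASTA/plain-text readers)."""
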