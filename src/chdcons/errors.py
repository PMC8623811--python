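"""Exception hierarchy shared across the package."""


class ChdconsError(Exception):
    """Base class for all package errors."""


class ParseError(ChdconsError):
    """A file or string could not be parsed (malformed header, bad HGVS token...)."""


class ValidationError(ChdconsError):
    """Parsed input violates a data-model invariant (illegal residue, overlapping domains...)."""


class FormatError(ChdconsError):
    """A structural problem in an alignment or matrix (ragged rows, asymmetry...)."""
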