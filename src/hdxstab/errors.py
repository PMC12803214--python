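"""Exception hierarchy shared by all hdxstab modules."""


class HdxStabError(Exception):
    """Base class for all package errors."""


class FormatError(HdxStabError):
    """A file could not be parsed (missing column, malformed row, bad FASTA...)."""


class ValidationError(HdxStabError):
    """Input values violate a domain invariant (sequence mismatch, bad centroid...)."""


class UsageError(HdxStabError):
    """The caller asked for something undefined (empty input, unknown label...)."""


class FitError(HdxStabError):
    """A nonlinear fit failed to converge; carries diagnostics in args."""
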