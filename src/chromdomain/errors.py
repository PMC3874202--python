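"""Exception hierarchy shared by all readers and analysis stages."""


class ChromDomainError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChromDomainError):
    """A file does not conform to the documented TSV/FASTA/BED dialect."""


class ValidationError(ChromDomainError):
    """A parsed table violates a documented invariant."""


class AnalysisError(ChromDomainError):
    """An analysis precondition is not met (e.g. no background proteins)."""
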