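"""Exception hierarchy for the acfsa package."""


class ACFSAError(Exception):
    """Base class for all package errors."""


class ValidationError(ACFSAError, ValueError):
    """Invalid or inconsistent input data."""


class FitError(ACFSAError, RuntimeError):
    """A numerical fit failed to converge; carries diagnostics in args."""
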