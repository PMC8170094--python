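"""Exception hierarchy shared by all analysis stages."""


class Bc1soxError(Exception):
    """Base class for all package errors."""


class ConfigError(Bc1soxError, ValueError):
    """Invalid configuration or parameter set."""


class AnomalousSpinError(Bc1soxError):
    """O2 spin density outside the recognized bands, or spin-sign mismatch."""


class UnattributableError(Bc1soxError):
    """Neither donor pool carries enough spin change to attribute the electron."""


class InsufficientReferenceError(Bc1soxError):
    """No (or too few) no-transfer snapshots to form a reference mean."""


class EstimationError(Bc1soxError):
    """A statistical fit or root-finding step failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CapabilityError(Bc1soxError):
    """A required optional input (coupling constant, z channel, ...) is absent."""
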