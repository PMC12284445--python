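"""Exception hierarchy shared across the package."""


class SdtmsError(Exception):
    """Base class for all package-specific errors."""


class SpecValidationError(SdtmsError, ValueError):
    """A parametric specification violated an invariant; names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DataQualityError(SdtmsError, ValueError):
    """Input data violate an assumption the analysis relies on."""


class FitError(SdtmsError, RuntimeError):
    """An optimizer failed to produce a usable fit; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class InversionError(SdtmsError, ValueError):
    """Threshold criterion falls outside the fitted curve's range."""


class ThresholdNotFoundError(SdtmsError, RuntimeError):
    """No qualifying intensity below the device ceiling."""


class SchemaError(SdtmsError, ValueError):
    """A tabular input is missing mandated columns or has bad types."""
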