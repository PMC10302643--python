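"""Exception hierarchy for kinetree."""


class KinetreeError(Exception):
    """Base class for all kinetree errors."""


class StructuralError(KinetreeError):
    """Ligand specification is not a valid connected phosphine graph."""


class UnsupportedElementError(KinetreeError):
    """Substituent contains an element outside the supported set (C only)."""


class CapacityError(KinetreeError):
    """Ligand tree does not fit the frozen graph template."""

    def __init__(self, message: str, layer: int | None = None):
        super().__init__(message)
        self.layer = layer


class UnknownSubstituentError(KinetreeError, LookupError):
    """Substituent symbol absent from the Hammett table."""


class UnsupportedPositionError(KinetreeError):
    """Substituent position outside {meta, para}."""


class ConstraintError(KinetreeError):
    """Model parameters violate a structural constraint (e.g. negativity)."""


class SchemaError(KinetreeError):
    """Input table is missing required columns."""


class RowValidationError(KinetreeError):
    """A table row fails validation; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class EmptyEnsembleError(KinetreeError):
    """No trained run met the ensemble selection thresholds."""


class DegenerateDesignError(KinetreeError):
    """Feature matrix is degenerate (e.g. all zeros)."""
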