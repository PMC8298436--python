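"""Exception types shared across the package."""


class MPRAError(Exception):
    """Base class for all package-specific errors."""


class DesignError(MPRAError):
    """Invalid or unconstructible library design (e.g. barcode space exhausted)."""


class SimulationError(MPRAError):
    """Invalid simulation request (missing truth entries, bad depth, ...)."""


class FilterError(MPRAError):
    """Invalid quantification input (e.g. a sample with zero RNA counts)."""


class InsufficientDataError(MPRAError):
    """Too few measurements/barcodes for the requested statistic."""


class MotifError(MPRAError):
    """Sequence/PWM mismatch (sequence shorter than motif, SNP off-center, ...)."""


class BedFormatError(MPRAError):
    """Malformed BED input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number
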