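"""Exception hierarchy for eqtlscan.

All user-facing failures derive from :class:`EqtlScanError` so the CLI can
catch one type and report the failing stage.
"""


class EqtlScanError(Exception):
    """Base class for all eqtlscan errors."""


class ParseError(EqtlScanError):
    """Malformed input file (bad column counts, half-missing calls, ...)."""


class DataError(EqtlScanError):
    """Inputs parsed but are scientifically invalid (e.g. >2 alleles at a SNP)."""


class SelectionError(EqtlScanError):
    """A subsetting operation selected nothing (empty region, unknown gene, ...)."""


class OutputError(EqtlScanError):
    """Refusing to clobber existing output, or an I/O failure with path context."""


class PipelineError(EqtlScanError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
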