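"""Exception hierarchy for the glycotrace pipeline."""


class GlycotraceError(Exception):
    """Base class for all pipeline errors."""


class AbifFormatError(GlycotraceError):
    """File is not a valid ABIF container (bad magic, bad header)."""


class AbifCorruptionError(GlycotraceError):
    """ABIF directory or payload is truncated or inconsistent."""


class ChannelNotFoundError(GlycotraceError):
    """Requested (tag, number) channel is absent from the record."""


class CoMigrationError(GlycotraceError):
    """Glycan and ladder channels have different lengths and cannot share a scan axis."""


class CalibrationError(GlycotraceError):
    """Ladder peak calling or migration-map fitting failed."""


class ParameterError(GlycotraceError):
    """Invalid processing parameter."""


class ExtrapolationError(GlycotraceError):
    """Requested region falls outside the calibrated migration span."""
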