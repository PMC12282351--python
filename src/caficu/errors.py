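"""Exception hierarchy.

Data-quality refusals (AF, short windows, missing leads) get their own types so
callers — in particular the CLI — can distinguish them from software errors.
"""


class CafIcuError(Exception):
    """Base class for all package errors."""


class RecordFormatError(CafIcuError):
    """Header/signal files missing, inconsistent, or in an unsupported format."""


class EmptyWindowError(CafIcuError):
    """Requested analysis window does not overlap the record."""


class WindowTooShortError(CafIcuError):
    """Overlap with the analysis window is below the configured minimum."""


class NoBeatsError(CafIcuError):
    """No plausible QRS complexes could be detected on any lead."""


class InsufficientDataError(CafIcuError):
    """Too few beats/intervals/samples for the requested computation."""


class InsufficientLeadsError(CafIcuError):
    """Fewer than three leads: the repolarization-vector analysis is unavailable
    and downstream scoring must take the DC-only path."""
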