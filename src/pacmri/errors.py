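"""Exception types for the RTPC analysis pipeline."""


class PacmriError(Exception):
    """Base class for package errors."""


class SimulationError(PacmriError, ValueError):
    """Inconsistent simulator configuration or degenerate sampling."""


class ReconstructionError(PacmriError, ValueError):
    """Malformed echo stream or invalid reconstruction request."""


class SegmentationError(PacmriError, RuntimeError):
    """No usable vessel region found (subject-level quality event)."""
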