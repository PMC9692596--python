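"""Exception hierarchy.

``ValidationError`` covers bad user input (exit code 2 at the CLI);
``CalibrationError`` and ``GenerationError`` are domain-specific failures.
"""


class SpioQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(SpioQuantError, ValueError):
    """Invalid input: bad geometry, degenerate histogram, empty ROI, ..."""


class CalibrationError(SpioQuantError):
    """Too few usable single particles to calibrate a footprint."""


class GenerationError(SpioQuantError):
    """A synthetic scene cannot be realized (e.g. infeasible packing)."""
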