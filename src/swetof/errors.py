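"""Exception and warning types shared across the pipeline.

Errors raised inside :func:`swetof.estimation.estimate_sws` carry a ``stage``
attribute naming the pipeline stage that failed, so batch drivers and the CLI
can report where an acquisition was lost instead of emitting a number.
"""

from __future__ import annotations


class SwetofError(Exception):
    """Base class for all package errors."""

    #: pipeline stage that raised the error, filled in by ``estimate_sws``
    stage: str | None = None


class ConfigurationError(SwetofError):
    """Invalid geometry/acquisition parameters or malformed config file."""


class InvalidWavefrontError(SwetofError):
    """Arrival times violate positivity or ascending order."""


class NoWavefrontError(SwetofError):
    """No detectable wave packet in the trace or field."""


class ImplausibleSpeedError(SwetofError):
    """Regression slope implies a speed outside the physical range."""


class AssignmentError(SwetofError):
    """Stage-1 nearest-prediction assignment could not produce four ordered wavefronts."""


class RefinementError(SwetofError):
    """Stage-2 combination search found no valid wavefront set."""


class ContainerFormatError(SwetofError):
    """HDF5 container missing datasets, of unknown type, or version-incompatible."""


class AliasingWarning(UserWarning):
    """Inter-frame phase at or beyond +/- pi: displacement is ambiguous."""


class PacketOverlapWarning(UserWarning):
    """Successive on-axis arrivals closer than one packet width."""


class CropWarning(UserWarning):
    """Requested crop exceeds the field extent; field returned unchanged."""
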