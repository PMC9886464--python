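"""Shared constants and exception types."""

from __future__ import annotations

#: Canonical class order used everywhere (confusion matrices, folders, reports).
CLASSES: tuple[str, ...] = ("AS", "MR", "MS", "MVP", "N")

#: The four valve pathologies (Normal excluded) over which macro-averages run.
DISEASE_CLASSES: tuple[str, ...] = ("AS", "MR", "MS", "MVP")


class PCGError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(PCGError, ValueError):
    """Invalid argument or precondition violation."""


class DegenerateInputError(ValidationError):
    """Input is formally valid but degenerate (constant signal, flat spectrum...)."""


class AudioIOError(PCGError, IOError):
    """Problem reading or writing an audio file."""
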