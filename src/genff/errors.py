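"""Exception hierarchy."""

from __future__ import annotations


class GenFFError(Exception):
    """Base class for all package errors."""


class UnsupportedElementError(GenFFError):
    """Raised for atomic numbers outside the supported 1..86 range."""

    def __init__(self, z: int):
        self.z = z
        super().__init__(f"unsupported element Z={z}: parameterized range is 1..86")


class ParseError(GenFFError):
    """Structure-file parsing failure; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class FitDivergedError(GenFFError):
    """Non-finite residual encountered during parameter fitting."""

    def __init__(self, message: str, x=None):
        self.x = x
        super().__init__(message)


class IllConditionedError(GenFFError):
    """EEQ system numerically singular; carries a condition estimate."""

    def __init__(self, cond: float):
        self.cond = cond
        super().__init__(f"EEQ linear system ill-conditioned (cond ~ {cond:.3e})")


class AlignmentError(GenFFError):
    """Structure superposition with mismatched atoms."""


class TrajectoryError(GenFFError):
    """Inconsistent or aborted trajectory."""

    def __init__(self, message: str, last_frame=None):
        self.last_frame = last_frame
        super().__init__(message)


class InsufficientSamplingError(GenFFError):
    """Too few trajectory frames for a distribution estimate."""
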