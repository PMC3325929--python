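"""Exception hierarchy shared across mtpop modules."""


class MtpopError(Exception):
    """Base class for all package-specific errors."""


class VariantParseError(MtpopError, ValueError):
    """A variant label could not be parsed; the message names the offending token."""


class PositionRangeError(MtpopError, ValueError):
    """A coordinate lies outside [1, reference length]."""


class MissingSequenceError(MtpopError, ValueError):
    """An operation required reference or sample bases that were not supplied."""


class ProfileConflictError(MtpopError, ValueError):
    """Two variants in one profile collide at the same reference site."""


class AlignmentFrameError(MtpopError, ValueError):
    """Sequences are not in the same alignment frame (length mismatch without gaps)."""


class MotifConfigError(MtpopError, ValueError):
    """A motif table is empty, duplicated, or uses unknown state symbols."""


class UndefinedStatisticError(MtpopError, ValueError):
    """A diversity statistic is undefined for the given sample size."""


class SaturationError(MtpopError, ValueError):
    """Requested mutation load would saturate the simulated genome."""


class StageError(MtpopError, RuntimeError):
    """A pipeline stage failed; carries the stage name and a distinct exit code."""

    def __init__(self, stage: str, exit_code: int, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code
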