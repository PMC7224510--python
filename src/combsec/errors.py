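"""Exception hierarchy shared across the package."""


class CombSecError(Exception):
    """Base class for all errors raised by this package."""


class PlateFormatError(CombSecError):
    """Malformed plate CSV or inconsistent well annotations."""


class MissingStateError(CombSecError):
    """A required (tissue, treatment, stimulation) cell state is absent."""


class QCError(CombSecError):
    """Quality-control step cannot be applied to the given plate."""


class DesignError(CombSecError):
    """Combination-design violation (e.g. non-exhaustive effect map)."""


class StageError(CombSecError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
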