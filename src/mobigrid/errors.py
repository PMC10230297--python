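"""Exception hierarchy shared across the pipeline stages."""


class MobigridError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MobigridError, ValueError):
    """An argument violates a precondition (range, emptiness, coverage)."""


class FormatError(MobigridError, ValueError):
    """An input file violates the expected schema or keying."""


class AlignmentError(MobigridError, ValueError):
    """Two series or tables cannot be date-aligned; names the offenders."""


class GeometryError(MobigridError, ValueError):
    """A vector feature carries invalid geometry; names the feature."""


class StageError(MobigridError, RuntimeError):
    """A pipeline stage failed; carries the stage name and its report."""

    def __init__(self, stage: str, message: str, report: dict | None = None):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
        self.report = report or {}
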