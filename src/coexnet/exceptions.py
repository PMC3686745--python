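"""Exception types shared across the pipeline."""


class CoexnetError(Exception):
    """Base class for package errors."""


class ParseError(CoexnetError, ValueError):
    """Malformed input table (ragged rows, duplicated headers, ...)."""


class LabelingError(CoexnetError, ValueError):
    """Sample/condition label problems (unknown sample id, missing label)."""


class StageError(CoexnetError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
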