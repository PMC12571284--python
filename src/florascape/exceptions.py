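"""Exception hierarchy shared across the pipeline."""


class FlorascapeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FlorascapeError):
    """Invalid configuration: bad simulation design, merge map, or run config."""


class ValidationError(FlorascapeError):
    """Invalid input data: malformed tables, unknown labels, domain violations."""


class StageError(FlorascapeError):
    """A pipeline stage failed; carries the stage name for CLI error reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
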