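"""Exception types shared across the pipeline."""


class InputError(ValueError):
    """Raised when input data or configuration cannot be used at all."""


class AnalysisError(RuntimeError):
    """Raised when a pipeline stage fails unrecoverably.

    Carries the name of the stage that failed so callers (and the CLI exit
    handler) can report where the analysis broke down.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
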