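"""Package-wide exception types."""


class ValidationError(ValueError):
    """An input value violates a structural or range constraint."""


class ScoringError(ValueError):
    """A questionnaire response cannot be scored (e.g. all items skipped)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
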