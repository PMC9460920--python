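"""Exception hierarchy shared by all pipeline stages."""


class PipelineError(Exception):
    """Base class for every error raised by this package."""


class FormatError(PipelineError):
    """A file violated its declared format (GMT, GCT, counts TSV, metadata)."""


class ValidationError(PipelineError):
    """An in-memory object violated an invariant (duplicate ids, bad config)."""


class StageError(PipelineError):
    """A pipeline stage failed; carries the stage name for the report.

    The message is always prefixed ``"<stage>: <reason>"`` so downstream
    tooling can attribute the failure without parsing tracebacks.
    """

    def __init__(self, stage: str, reason: str):
        self.stage = stage
        self.reason = reason
        super().__init__(f"{stage}: {reason}")
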