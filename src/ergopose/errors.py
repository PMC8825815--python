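"""Exception hierarchy for the ergopose package."""


class ErgoposeError(Exception):
    """Base class for all package errors."""


class ValidationError(ErgoposeError):
    """A domain-type invariant was violated."""


class FormatError(ErgoposeError):
    """An input file does not follow the expected keypoint format."""


class PipelineError(ErgoposeError):
    """End-to-end assessment could not be completed."""
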