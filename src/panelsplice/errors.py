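"""Exception types shared across the pipeline."""


class PanelspliceError(Exception):
    """Base class for all panelsplice errors."""


class AnnotationError(PanelspliceError):
    """Raised for unusable panel or GTF annotation input."""


class FormatError(PanelspliceError):
    """Raised for malformed tabular input files."""


class PipelineError(PanelspliceError):
    """Raised when a pipeline stage cannot run (missing inputs, id mismatches)."""
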