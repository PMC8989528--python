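"""Exception types shared across the pipeline."""


class ConstructDefinitionError(ValueError):
    """A construct sheet or oligo definition violates the assay layout
    (wrong oligo length, missing lesion placeholder, duplicate barcode...)."""


class ConfigurationError(ValueError):
    """A run parameter is outside its documented range or inconsistent with
    the construct geometry (e.g. amplicon window shorter than the reads)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed or an internal accounting invariant broke."""
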