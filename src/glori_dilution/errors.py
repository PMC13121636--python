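"""Exception hierarchy for the pipeline.

QC failure (a sample not meeting the conversion threshold) is reported in the
result object, not raised; ``QCError`` is reserved for situations where QC
cannot be computed at all (e.g. no spike-in coverage).
"""


class GloriDilutionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GloriDilutionError):
    """Invalid simulation or run configuration."""


class InputError(GloriDilutionError):
    """Malformed input data (negative counts, bad pentamer, ...)."""


class QCError(GloriDilutionError):
    """Conversion QC could not be computed (distinct from a QC failure)."""


class PipelineError(GloriDilutionError):
    """A pipeline stage failed; message names the stage and cause."""
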