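"""Exception types raised across the pipeline."""

from __future__ import annotations


class GliohubError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GliohubError):
    """Invalid simulation or pipeline configuration."""


class FormatError(GliohubError):
    """Malformed input file; message names the offending row/column."""


class EmptyResultError(GliohubError):
    """An operation removed or filtered everything."""


class DegenerateInputError(GliohubError):
    """Input admits no meaningful statistic (constant data, no events, ...)."""


class NoQualifyingPowerError(GliohubError):
    """No candidate soft-threshold power reached the scale-free fit cutoff.

    Carries the full scan table so the caller can inspect it and, if it
    chooses, relax the cutoff.
    """

    def __init__(self, message: str, scan=None):
        super().__init__(message)
        self.scan = scan


class PipelineStageError(GliohubError):
    """A pipeline stage failed; names the stage and keeps partial artifacts."""

    def __init__(self, stage: str, message: str, manifest=None):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
        self.manifest = manifest or []
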