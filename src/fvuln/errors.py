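"""Exception hierarchy.

``ValidationError`` covers malformed inputs and configuration (CLI exit
code 1); everything else raised by the package is a ``PipelineError``
subclass (CLI exit code 2).
"""


class FvulnError(Exception):
    """Base class for all package errors."""


class ValidationError(FvulnError, ValueError):
    """Invalid input data or configuration; the message names the offender."""


class DegenerateHullError(FvulnError):
    """A point set does not support a full-dimensional convex hull."""


class PipelineError(FvulnError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
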