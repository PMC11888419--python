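"""Exception hierarchy.

``ParameterError`` signals invalid user-supplied parameters or
configuration; ``AnalysisError`` signals that an analysis step could not
produce a result from otherwise valid inputs (empty mask, degenerate
data, failed correlation).
"""


class EhtMechError(Exception):
    """Base class for all package errors."""


class ParameterError(EhtMechError, ValueError):
    """Invalid parameter, specification or configuration value."""


class AnalysisError(EhtMechError, RuntimeError):
    """An analysis stage failed on otherwise well-formed inputs."""
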