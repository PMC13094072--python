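"""Exception hierarchy.

Two broad families matter to callers (and to the CLI exit codes):
``InputError`` for anything wrong with files, configs or parameters, and
``ComputationError`` for analyses that fail on structurally valid input
(e.g. no detectable strike plateau).
"""


class StrikeLabError(Exception):
    """Base class for all package errors."""


class InputError(StrikeLabError):
    """Invalid input: files, configuration or parameters."""


class ValidationError(InputError):
    """A scenario/config/data field violates its invariant.

    Carries ``field`` so callers can see which invariant failed.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class FormatError(InputError):
    """A file does not parse as the expected dialect."""


class ConfigurationError(InputError):
    """Required configuration (scale, body mass, muscle mass ...) missing."""


class ParameterError(InputError):
    """An analysis parameter is out of range (e.g. even smoothing window)."""


class ComputationError(StrikeLabError):
    """An analysis step failed on otherwise valid input."""


class DegenerateGeometryError(ComputationError):
    """Coincident landmarks make a joint angle undefined."""

    def __init__(self, frame: int, joint: str):
        self.frame = frame
        self.joint = joint
        super().__init__(
            f"degenerate geometry at frame {frame}: zero-length vector at "
            f"{joint} joint (coincident landmarks)"
        )


class SegmentationError(ComputationError):
    """Strike phases could not be identified; message carries diagnostics."""


class NoStrikeError(ComputationError):
    """A force trace contains no detectable strike transient."""


class ModelFitError(ComputationError):
    """Mixed-model fitting failed (rank deficiency, missing cells ...)."""
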