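"""Exception hierarchy for the gaitpose pipeline.

Structural problems (bad files, bad configuration, impossible parameters)
raise; data-quality problems (a joint over the missing limit, an empty bout)
are reported through flags and warnings so batch runs can continue.
"""


class GaitPoseError(Exception):
    """Base class for all gaitpose errors."""


class FormatError(GaitPoseError):
    """An input file could not be parsed as the declared dialect."""


class ConfigurationError(GaitPoseError):
    """An unknown dialect, tracker label, or invalid configuration value."""


class UnrecoverableJointError(GaitPoseError):
    """A joint has no confident observation anywhere in the trajectory."""

    def __init__(self, joint: str):
        self.joint = joint
        super().__init__(f"joint {joint!r} has no confident observations; cannot interpolate")


class AnnotationError(GaitPoseError):
    """Bout annotations are out of range or overlapping."""


class ParameterError(GaitPoseError):
    """A numeric parameter is outside its valid domain."""


class TooShortError(GaitPoseError):
    """A trajectory is too short for the requested operation."""


class AlignmentError(GaitPoseError):
    """Cross-system step sequences could not be aligned."""


class MetadataError(GaitPoseError):
    """Required subject metadata (height, leg length) is missing."""


class PairingError(GaitPoseError):
    """Paired statistical inputs have mismatched lengths."""


class InsufficientDataError(GaitPoseError):
    """Too few values for the requested statistic."""


class UndefinedStatisticError(GaitPoseError):
    """The statistic is undefined for this input (zero variance or zero mean)."""
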