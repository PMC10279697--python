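"""Exception and warning types shared across the package."""


class CingradError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CingradError, ValueError):
    """A configuration field is missing, out of range, or inconsistent."""


class AlignmentError(CingradError, ValueError):
    """Two objects that must share a voxel set or grid do not."""


class DegenerateDataError(CingradError, ValueError):
    """An input is degenerate (constant map, all-zero spectrum, ...)."""


class PipelineStageError(CingradError, RuntimeError):
    """A pipeline stage failed; the stage name is carried in the message."""


class DegenerateVoxelWarning(UserWarning):
    """A voxel had zero variance and was zeroed / left unassigned."""


class TieBreakWarning(UserWarning):
    """A deterministic tie-break rule was applied (argmax ties, peak ties)."""


class EmptyNetworkWarning(UserWarning):
    """A network label had no member voxels and was skipped."""


class DisconnectedGraphWarning(UserWarning):
    """The affinity graph has more than one connected component."""


class RankDeficiencyWarning(UserWarning):
    """Linearly dependent confound columns were dropped before regression."""
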