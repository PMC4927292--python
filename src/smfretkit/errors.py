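"""Exception hierarchy shared across the pipeline stages."""


class SmfretError(Exception):
    """Base class for all errors raised by smfretkit."""


class ConfigError(SmfretError, ValueError):
    """A configuration object or file failed validation."""


class AnalysisError(SmfretError, RuntimeError):
    """An analysis step could not be completed on the given data."""


class BleachDetectionError(AnalysisError):
    """Photobleaching-step detection preconditions were not met."""


class GammaEstimationError(AnalysisError):
    """Per-molecule gamma estimation failed (no acceptor bleach, or a
    non-positive donor step)."""


class FitError(AnalysisError):
    """A model fit failed or did not converge."""


class OcclusionError(AnalysisError):
    """A dye labelling site is sterically occluded: no allowed dye
    position was found within the attempt budget."""
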