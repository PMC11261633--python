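"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """An input object violates one of its declared invariants."""


class ConfigurationError(ValidationError):
    """A configuration or geometry parameter set is inconsistent."""


class FormatError(ValueError):
    """A file on disk could not be parsed into the expected structure."""


class EmptyROIError(ValueError):
    """An ROI contains no valid (non-missing) voxels after thresholding."""


class TroughNotFoundError(RuntimeError):
    """No qualifying marker trough was found; caller should fall back to a
    manually supplied AIS interval."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""
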