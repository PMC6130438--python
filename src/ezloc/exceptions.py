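"""Exception hierarchy for the ezloc pipeline."""


class EzlocError(Exception):
    """Base class for all ezloc errors."""


class FormatError(EzlocError, ValueError):
    """A file or in-memory container violates the expected format."""


class AnnotationError(EzlocError, ValueError):
    """Seizure/channel annotations are inconsistent with the recording."""


class ConfigurationError(EzlocError, ValueError):
    """A parameter combination is invalid (e.g. stop band above Nyquist)."""


class DataError(EzlocError, ValueError):
    """The data are too short/degenerate for the requested operation."""


class TrainingError(EzlocError, ValueError):
    """Model fitting received degenerate or insufficient training data."""


class ScoringError(EzlocError, ValueError):
    """Agreement statistic undefined for the given electrode sets."""
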