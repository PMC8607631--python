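"""Exception hierarchy for the phonation-analysis pipeline."""


class ParavoxError(Exception):
    """Base class for all package-specific errors."""


class AudioFormatError(ParavoxError):
    """The file is not a readable RIFF/WAVE PCM or float recording."""


class EmptyInputError(ParavoxError):
    """The recording contains no samples."""


class InsufficientVoicingError(ParavoxError):
    """Less than one second of above-threshold material in the recording.

    Carries the measured voiced duration in seconds as ``voiced_s``.
    """

    def __init__(self, voiced_s: float):
        self.voiced_s = float(voiced_s)
        super().__init__(
            f"recording contains only {self.voiced_s:.3f} s of voiced material; "
            "at least 1 s is required"
        )


class UnvoicedSignalError(ParavoxError):
    """No periodic structure found in the fundamental-frequency search band."""


class InsufficientCyclesError(ParavoxError):
    """Too few glottal cycles for a perturbation measure."""


class InsufficientDataError(ParavoxError):
    """Too few frames/samples for the requested measure."""


class SpecError(ParavoxError, ValueError):
    """Invalid synthesis or cohort specification."""


class SchemaError(ParavoxError):
    """Feature-table schema violation (unknown/missing columns, name mismatch)."""


class TableParseError(SchemaError):
    """CSV feature table could not be parsed; carries the offending row."""


class ConsistencyError(ParavoxError):
    """Conflicting labels or sex within a subject."""


class StratificationError(ParavoxError):
    """A class has fewer members than the number of folds."""


class SelectionError(ParavoxError):
    """Feature selection cannot run (degenerate labels, <2 features)."""


class UndefinedMetricError(ParavoxError):
    """Metric undefined for the given inputs (e.g. single-class labels)."""
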