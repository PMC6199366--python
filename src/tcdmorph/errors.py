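"""Exception hierarchy shared across the package."""


class TcdError(Exception):
    """Base class for all tcdmorph errors."""


class FormatError(TcdError, ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(TcdError, ValueError):
    """A domain object violates one of its invariants."""


class NoBeatsError(TcdError):
    """No pulsatile beats could be detected in a recording."""


class NoUsableBeatsError(TcdError):
    """Every detected beat was rejected by quality control."""


class IncompleteExamError(TcdError):
    """An exam lacks a usable recording for at least one hemisphere."""


class DegenerateBeatError(TcdError):
    """A beat waveform is flat (no diastolic-systolic range)."""
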