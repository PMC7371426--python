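"""Named exceptions raised across the pipeline.

Each error corresponds to a distinct contract violation so callers can
discriminate failure modes without string matching.
"""


class PersistfireError(Exception):
    """Base class for all package errors."""


# ---------------------------------------------------------------- native I/O
class NativeFormatError(PersistfireError):
    """Base class for on-disk cohort format violations."""


class MissingMetadataError(NativeFormatError):
    """A required key is absent from a JSON metadata file."""


class SeriesLengthMismatchError(NativeFormatError):
    """A series file's row count disagrees with its declared length."""


class NonMonotonicTimeError(NativeFormatError):
    """A time column is not strictly increasing."""


# ----------------------------------------------------------------- ABF adapter
class ABFAdapterError(PersistfireError):
    """Base class for the optional ABF reader."""


class ABFSupportError(ABFAdapterError):
    """pyabf is unavailable or the file layout/version is unsupported."""


class MissingChannelError(ABFAdapterError):
    """The requested channel is absent from the ABF file."""


# ------------------------------------------------------------- spike analysis
class SampleRateTooLowError(PersistfireError):
    """Sampling rate is too low to estimate dV/dt (< 2 kHz)."""


class SingularFitError(PersistfireError):
    """A regression cannot be fit (e.g. identical current levels)."""


# -------------------------------------------------------- persistence metrics
class ExcludedCellError(PersistfireError):
    """The cell has 0% firing probability and is excluded from rate metrics."""


# -------------------------------------------------------- subthreshold metrics
class SpikeContaminationError(PersistfireError):
    """Post-offset action potentials detected in a subthreshold-only sweep."""


class WindowOutOfRangeError(PersistfireError):
    """A measurement window extends past the end of the sweep."""


# ------------------------------------------------------------------- behavior
class InsufficientBaselineError(PersistfireError):
    """Trial has less pre-CS baseline than the scoring rule requires."""


class UnscoreableTrialError(PersistfireError):
    """Trial type is never scored for conditioned responses (us_alone)."""
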