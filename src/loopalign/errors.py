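"""Exception hierarchy for loopalign.

Hardware-style faults (mount, motors) and algorithmic failures (segmentation,
fitting, convergence) are kept distinct so the orchestrator can map them onto
per-step statuses.
"""


class LoopAlignError(Exception):
    """Base class for all loopalign errors."""


# --- virtual beamline -------------------------------------------------------

class MountFailure(LoopAlignError):
    """The (simulated) sample changer failed to mount the pin."""


class NoSampleMounted(LoopAlignError):
    """An operation requiring a mounted sample was called on an empty goniometer."""


class MotorLimit(LoopAlignError):
    """A requested motor target lies outside the configured soft limits."""


# --- vision / centering -----------------------------------------------------

class LoopNotFound(LoopAlignError):
    """No loop silhouette could be segmented from the camera frame."""


class CalibrationFailure(LoopAlignError):
    """Top-camera beam-marker calibration could not segment its reference object."""


class ConvergenceFailure(LoopAlignError):
    """Tip alignment residual stayed above tolerance after the refinement rounds."""


class DegenerateFit(LoopAlignError):
    """The projected-area sinusoid has no usable modulation (near-spherical sample)."""


class NotCentered(LoopAlignError):
    """A grid was requested from a centering result that is not in the centered state."""


# --- grid scan --------------------------------------------------------------

class EmptyGrid(LoopAlignError):
    """A best-box selection was requested on a grid with no boxes."""


# --- orchestration ----------------------------------------------------------

class UnknownMethod(LoopAlignError):
    """Collection method name not in the supported set."""


class AutomationStopped(LoopAlignError):
    """A step failed; the whole run halts.  Carries the failing row and step."""

    def __init__(self, row: int, step: str, message: str = ""):
        self.row = row
        self.step = step
        super().__init__(f"automation stopped at row {row}, step {step}: {message}")


class AcquisitionFailure(LoopAlignError):
    """Simulated detector/disk fault during data acquisition."""


class CorruptJournal(LoopAlignError):
    """The run journal cannot be replayed (malformed or truncated record)."""


class Interrupted(LoopAlignError):
    """Simulated process crash at a step boundary (used to exercise resume)."""


# --- spreadsheet ------------------------------------------------------------

class MissingColumn(LoopAlignError):
    """A required spreadsheet column is absent."""


class SpreadsheetInvalid(LoopAlignError):
    """The spreadsheet failed validation; carries the full error report."""

    def __init__(self, report):
        self.report = report
        super().__init__(f"spreadsheet validation failed with {len(report.errors)} error(s)")
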