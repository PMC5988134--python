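"""Exception types shared across the package."""


class SpectriageError(Exception):
    """Base class for all package errors."""


class ParameterError(SpectriageError, ValueError):
    """A model input violates its constraints.

    Carries the dotted path of the offending field (e.g. ``cohort.prevalence``)
    so configuration mistakes are reported by name.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class TreeStructureError(SpectriageError, ValueError):
    """A decision tree violates a structural invariant (e.g. branch
    probabilities that do not sum to one)."""


class CalibrationError(SpectriageError, ValueError):
    """A calibration target cannot identify the requested constant
    (e.g. no skipped-work-up mass in the secondary-care scenario)."""
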