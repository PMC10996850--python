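"""Exception hierarchy for the RMDV pipeline."""


class RmdvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RmdvError, ValueError):
    """Invalid cohort / phantom / run configuration."""


class GeometryError(RmdvError, ValueError):
    """Phantom geometry is inconsistent (overlapping lesion and sinus, etc.)."""


class InputError(RmdvError, ValueError):
    """Malformed or empty input to a measurement or tabulation step."""


class MeasurementError(RmdvError, ValueError):
    """A density measurement is physically implausible or impossible."""


class SinusUnmeasurableError(MeasurementError):
    """The sinus reference mask is fully excluded by the skull/artifact rule."""


class FollowupMissingError(RmdvError, ValueError):
    """No 24 h follow-up image; the case must be excluded from adjudication."""


class DegenerateTableError(RmdvError, ValueError):
    """A 2x2 margin is zero, so a requested statistic is undefined."""


class SchemaError(RmdvError, ValueError):
    """A CSV input does not have the expected columns or row format."""
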