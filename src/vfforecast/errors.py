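"""Exception hierarchy for the VF-forecasting pipeline."""


class VFForecastError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(VFForecastError, ValueError):
    """A generator or model parameter violates its contract."""


class InsufficientDataError(VFForecastError, ValueError):
    """Too few beats/intervals/samples for the requested computation."""


class RecordExcludedError(VFForecastError):
    """A record cannot provide the required analysis window.

    Mirrors the study-design exclusion of recordings shorter than the
    required pre-onset length; carries the record id for reporting.
    """

    def __init__(self, record_id: str, reason: str):
        self.record_id = record_id
        self.reason = reason
        super().__init__(f"record {record_id!r} excluded: {reason}")


class FormatError(VFForecastError, ValueError):
    """A file on disk is malformed or internally inconsistent."""


class ZeroVarianceError(VFForecastError, ValueError):
    """A feature has zero variance and cannot be standardized."""

    def __init__(self, feature: str):
        self.feature = feature
        super().__init__(f"feature {feature!r} has zero variance in the training set")
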