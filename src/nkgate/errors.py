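"""Exception hierarchy for the nkgate pipeline."""


class NKGateError(Exception):
    """Base class for all nkgate errors."""


class PanelMismatchError(NKGateError):
    """A marker referenced by a strategy, perturbation or config is absent from the panel."""


class ConfigurationError(NKGateError):
    """An invalid run/cohort configuration (unknown condition, missing threshold, ...)."""


class InsufficientDataError(NKGateError):
    """Too few observations to carry out an estimate or a test."""


class DegenerateDataError(NKGateError):
    """Input data carries no usable signal (e.g. all values identical)."""
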