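"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter violates its documented domain (non-positive rate, empty list, ...)."""


class UnusableTraceError(RuntimeError):
    """Every sample of an eye trace was flagged as saccadic; nothing remains to analyze."""


class InsufficientDataError(RuntimeError):
    """Fewer samples, trials, or cycles than the analysis requires."""


class DegenerateBaselineError(RuntimeError):
    """Baseline fluorescence F0 <= 0, so dF/F is undefined."""


class UndefinedMetricError(RuntimeError):
    """A ratio metric hit a 0/0 or zero-denominator case."""


class MissingGroupError(RuntimeError):
    """A direction group required by a population-level computation is empty."""
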