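"""Exception hierarchy shared across the package.

Undefined numerical results (e.g. LF/HF when HF power is exactly zero, or
sample entropy with no template matches at order m+1) are *not* exceptions:
they are reported as NaN so cohort tables can carry them as missing values.
Exceptions are reserved for contract violations on inputs.
"""


class HRVError(ValueError):
    """Base class for all input-contract violations."""


class InvalidProfileError(HRVError):
    """A synthesis profile violates its invariants (e.g. mean_rr <= 0)."""


class InsufficientDataError(HRVError):
    """Too few beats/samples for the requested statistic."""


class ParameterError(HRVError):
    """An analysis parameter is out of its documented range."""


class OverlapError(HRVError):
    """QRS template wider than the shortest RR interval."""


class InternalConsistencyError(RuntimeError):
    """Two mathematically equivalent routes disagreed beyond tolerance."""
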