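"""Exception types shared across the pipeline."""


class PlaquestratError(Exception):
    """Base class for package errors."""


class ParameterError(PlaquestratError, ValueError):
    """An argument or simulation parameter violates its invariant."""


class StateError(PlaquestratError, RuntimeError):
    """Inputs are structurally valid but the operation cannot proceed
    (e.g. no patients survive exclusion, group labels missing)."""


class DegenerateDataError(PlaquestratError, ValueError):
    """Data carry no information for the requested fit (e.g. all
    observations identical with k > 1)."""


class DesignError(PlaquestratError, ValueError):
    """A model design matrix is singular or a required cell is empty."""


class ThresholdError(PlaquestratError, RuntimeError):
    """No density intersection exists between the component means;
    classify by posterior responsibility instead."""
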