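"""Exception hierarchy for curescan."""


class CurescanError(Exception):
    """Base class for all curescan errors."""


class DataFormatError(CurescanError):
    """Malformed or inconsistent input files (genotype or clinical)."""


class UndefinedInputError(CurescanError):
    """A statistic is undefined for the given input (e.g. all-missing vector)."""


class NoEventsError(CurescanError):
    """A survival fit was requested on data without any events."""


class CollinearityError(CurescanError):
    """The design matrix is (numerically) rank deficient."""


class ConvergenceError(CurescanError):
    """An optimizer diverged where the contract requires an error."""


class DegenerateWeightsError(CurescanError):
    """EM susceptibility weights degenerate (e.g. all zero)."""
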