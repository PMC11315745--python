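"""Exception hierarchy.

Every error the library raises derives from :class:`VtecostError`, so callers
(and the CLI's exit-code mapping) can distinguish configuration problems,
infeasible simulation constraints and degenerate data from programming errors.
"""


class VtecostError(Exception):
    """Base class for all package errors."""


class ConfigError(VtecostError):
    """Invalid or inconsistent configuration / input file."""


class InvalidSummaryError(ConfigError):
    """Quantile summary (median/IQR) is non-positive or disordered."""


class CohortParseError(ConfigError):
    """A cohort CSV row is malformed; message carries the line number."""


class ConstraintInfeasibleError(VtecostError):
    """A cohort constraint set cannot be satisfied; message names the group."""


class InfeasibleTruncationError(ConstraintInfeasibleError):
    """Requested truncation interval carries (practically) zero probability mass."""


class UnresolvedRuleError(VtecostError):
    """A data-derived cut-off rule was used before being resolved on a cohort."""


class DegenerateDataError(VtecostError):
    """Data lacks the cases/controls or variation required by an estimator."""
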