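"""Exception hierarchy shared across clinicflow modules."""


class ClinicFlowError(Exception):
    """Base class for all clinicflow errors."""


class ConfigurationError(ClinicFlowError):
    """An invalid distribution, scenario, or template parameter."""


class MomentUndefinedError(ClinicFlowError):
    """A requested moment does not exist for the given parameters."""


class SampleSizeError(ClinicFlowError):
    """Too few observations to attempt a distribution fit."""


class DegenerateDataError(ClinicFlowError):
    """Zero-variance (or otherwise degenerate) data passed to a fitter."""


class ConstraintViolationError(ConfigurationError):
    """A scenario parameter falls outside its search-space bound."""


class NoFeasibleConfigurationError(ClinicFlowError):
    """Every point in an optimization search space violated the deadline."""
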