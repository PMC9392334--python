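"""Exception taxonomy shared across the package."""


class ClusterNIError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ClusterNIError, ValueError):
    """A scenario, run-config or sampler-config field is out of range."""


class ParseError(ClusterNIError, ValueError):
    """A CSV input could not be parsed; message carries the line number."""


class ValidationError(ClusterNIError, ValueError):
    """An input value is syntactically fine but semantically invalid."""


class ConsistencyError(ClusterNIError, ValueError):
    """Cross-record inconsistency, e.g. one teacher mapped to two schools."""


class ModelError(ClusterNIError, ValueError):
    """The requested model cannot be fit to the supplied dataset."""


class DegenerateLikelihoodError(ModelError):
    """A two-part likelihood has an empty part (all-zero or all-positive)."""


class InitialisationError(ClusterNIError, ValueError):
    """Log-density non-finite at the sampler's initial point."""


class DiagnosticError(ClusterNIError, ValueError):
    """Convergence diagnostic requested on unsuitable draws (e.g. 1 chain)."""


class SummaryError(ClusterNIError, ValueError):
    """Posterior summary requested on too few draws."""


class BootstrapError(ClusterNIError, ValueError):
    """Bootstrap resampling impossible (e.g. a single school in an arm)."""


class PipelineError(ClusterNIError, RuntimeError):
    """A pipeline stage failed; message is stage-labelled."""
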