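"""Exception types shared across graphsurv modules."""


class GraphsurvError(Exception):
    """Base class for all graphsurv errors."""


class ConfigurationError(GraphsurvError, ValueError):
    """A configuration value violates a stated bound."""


class EmptyGraphError(GraphsurvError):
    """A slide produced no usable imaging-graph (no foreground / one node)."""


class GraphFormatError(GraphsurvError):
    """A graph container file is missing a required field."""


class EmptyMatrixError(GraphsurvError):
    """Gene filtering removed every gene."""


class SignatureMatchError(GraphsurvError):
    """A gene signature matched no genes in the expression matrix."""


class UndefinedMetricError(GraphsurvError):
    """A metric has no comparable pairs / valid evaluation points."""
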