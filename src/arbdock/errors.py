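"""Exception hierarchy shared across the package."""


class ArbdockError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ArbdockError):
    """A file could not be parsed in the expected format."""


class EmptyInputError(ArbdockError):
    """An input that must contain data was empty."""


class SelectionError(ArbdockError):
    """A residue/atom selection did not resolve against a structure."""


class TopologyError(ArbdockError):
    """Structures that must share topology (atom count/ordering) do not."""


class ParameterError(ArbdockError):
    """A generator or algorithm parameter is out of its valid range."""


class CompletenessError(ArbdockError):
    """A rectangular data grid has missing or duplicate cells."""


class DomainError(ArbdockError):
    """A fitted surface was evaluated outside its bounding rectangle."""


class InsufficientDataError(ArbdockError):
    """Not enough observations for the requested statistic."""
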