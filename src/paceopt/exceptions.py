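"""Exception hierarchy for paceopt."""


class PaceoptError(Exception):
    """Base class for all paceopt errors."""


class RosterError(PaceoptError):
    """A current name outside the eleven-term roster was requested."""


class StateIntegrityError(PaceoptError):
    """A cell state violates its invariants (gate out of [0,1], conc <= 0)."""


class QuiescentModelError(PaceoptError):
    """An operation that requires a beating model received a quiescent one."""


class InsufficientCyclesError(PaceoptError):
    """A trace does not contain enough complete cycles for the operation."""


class ConfigError(PaceoptError):
    """Invalid run configuration."""


class FormatError(PaceoptError):
    """Malformed delimited-text trace or table file."""


class ShortfallError(PaceoptError):
    """Fewer usable optimization runs than a statistic requires."""


class DegenerateInputError(PaceoptError):
    """Zero-variance or rank-deficient input to a statistical routine."""
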