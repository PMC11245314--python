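"""Exception hierarchy.

Everything raised on purpose derives from :class:`ChordwalkError` so callers can
catch the whole family; most classes also derive from ``ValueError`` because
they signal bad inputs.
"""


class ChordwalkError(Exception):
    """Base class for all chordwalk errors."""


class DimensionError(ChordwalkError, ValueError):
    """Shapes of vectors/matrices do not line up."""


class FeasibilityError(ChordwalkError, ValueError):
    """A point or polytope fails a feasibility requirement."""


class InfeasibleError(FeasibilityError):
    """The polytope is empty (the feasibility LP has no solution)."""


class UnboundedError(ChordwalkError, ValueError):
    """The polytope (or a chord through it) is unbounded."""


class DegenerateError(ChordwalkError, ValueError):
    """The feasible set has an empty interior (e.g. a single point)."""


class InconsistentError(ChordwalkError, ValueError):
    """An equality system S·x = c has no solution."""


class PluginError(ChordwalkError, RuntimeError):
    """A user-supplied log-density misbehaved (NaN, wrong shape, ...)."""


class ContractError(ChordwalkError, TypeError):
    """An object does not satisfy the model or proposal contract."""


class RegistryError(ChordwalkError, KeyError):
    """Unknown proposal name."""


class NotTunableError(ChordwalkError, ValueError):
    """The proposal exposes no step size to tune."""


class UnsupportedTargetError(ChordwalkError, ValueError):
    """The proposal is only valid for a restricted class of targets."""


class CheckpointError(ChordwalkError, RuntimeError):
    """A checkpoint blob is corrupted or from an incompatible schema."""


class ConfigError(ChordwalkError, ValueError):
    """A configuration document is malformed."""
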