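"""Exception hierarchy for tipstalk.

All failures that a caller may want to branch on are typed; numerical
"not found" outcomes (a pattern that has no root at given parameters)
are data values, not exceptions.
"""


class TipstalkError(Exception):
    """Base class for all tipstalk errors."""


class InvalidParameterError(TipstalkError, ValueError):
    """A model or operation parameter violates its invariant."""


class InvalidStateError(TipstalkError, ValueError):
    """A lattice state is outside the admissible manifold (NaN, negative
    Delta, Notch fraction outside [0, 1], mismatched lengths)."""


class DegenerateInterfaceError(TipstalkError, ArithmeticError):
    """The interface-distance denominator vanished: a fully bound,
    ligand-free cell-cell contact has no defined intercellular distance."""


class UnsupportedVariantError(TipstalkError, TypeError):
    """The operation does not apply to this model variant."""


class IncompatibleLatticeError(TipstalkError, ValueError):
    """The requested pattern period does not divide the lattice size."""


class NumericalFailureError(TipstalkError, RuntimeError):
    """A numerical routine failed where failure is not a data value
    (e.g. no bracket for the uniform state, integrator breakdown)."""


class ConfigError(TipstalkError, ValueError):
    """A run configuration file is malformed; message carries the key path."""
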