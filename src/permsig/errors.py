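"""Exception hierarchy shared across the package.

Input problems (malformed files, inconsistent labels, impossible splits) raise
:class:`InputError`; numerical degeneracies (collapsed mixture components,
empty classifier pools) raise :class:`NumericalError`.  The CLI maps these to
exit codes 2 and 3 respectively.
"""


class PermsigError(Exception):
    """Base class for all package errors."""


class InputError(PermsigError, ValueError):
    """Malformed or inconsistent user input."""


class NumericalError(PermsigError, RuntimeError):
    """Numerical failure (degenerate fit, no usable classifier, ...)."""


class DegenerateFitError(NumericalError):
    """A mixture component collapsed (variance below the floor) or the
    input has too little spread to support a two-component fit."""
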