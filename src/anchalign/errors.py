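"""Exception hierarchy.

All package errors derive from :class:`AnchalignError` so callers can catch
one base class; the leaf classes also derive from the matching builtin
(``ValueError``, ``KeyError``, ``RuntimeError``) so idiomatic handling works.
"""


class AnchalignError(Exception):
    """Base class for all anchalign errors."""


class InvalidSequenceError(AnchalignError, ValueError):
    """A sequence contains characters outside the DNA alphabet A/C/G/T."""


class DuplicateIdError(AnchalignError, KeyError):
    """A record id collides with one already stored."""


class ParameterError(AnchalignError, ValueError):
    """A parameter is out of its valid range (e.g. sample size z)."""


class StateError(AnchalignError, RuntimeError):
    """An operation was invoked in an invalid store state (e.g. empty sample)."""


class ContractError(AnchalignError, ValueError):
    """An internal contract was violated (e.g. unequal alignment rows)."""
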