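"""Exception hierarchy.

CLI exit-code mapping: InputError -> 2, InternalConsistencyError -> 3.
"""


class CoaxfoldError(Exception):
    """Base class for all package errors."""


class InputError(CoaxfoldError, ValueError):
    """Invalid user-supplied input (sequence, structure text, config file)."""


class NonCanonicalPairError(InputError):
    """A base pair outside the canonical set {AU, UA, GC, CG, GU, UG}."""


class InternalConsistencyError(CoaxfoldError):
    """A should-be-unreachable state (e.g. corrupted DP backpointers)."""
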