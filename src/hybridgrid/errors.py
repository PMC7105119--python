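"""Exception types raised by defensive checks across the library."""


class OccupancyError(RuntimeError):
    """Two unstackable agents would share a lattice position."""


class StabilityError(ValueError):
    """A finite-difference rate constant violates its stability bound."""


class StateError(RuntimeError):
    """An object is used in a state that forbids the operation."""
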