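"""Exception types shared across the package."""


class StructuralError(ValueError):
    """Raised when an input violates a structural contract.

    Covers shape mismatches, incomplete branch sets, empty catalogs,
    non-stochastic profile rows, and similar malformed-input conditions —
    anything that makes the requested computation ill-posed rather than
    merely numerically awkward.
    """
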