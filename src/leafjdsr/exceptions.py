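"""Exception hierarchy for leafjdsr.

All errors derive from :class:`LeafJDSRError` so callers can catch the
package's failures with a single ``except`` clause; the concrete classes
also subclass :class:`ValueError` for drop-in compatibility with numpy/sklearn
style validation errors.
"""


class LeafJDSRError(Exception):
    """Base class for all leafjdsr errors."""


class InvalidInputError(LeafJDSRError, ValueError):
    """An argument violates a precondition (shape, dtype, range, emptiness)."""


class DegenerateImageError(LeafJDSRError, ValueError):
    """An image has no usable foreground (empty mask or zero-extent crop)."""


class DegeneratePairError(LeafJDSRError, ValueError):
    """Jaccard comparison of two all-zero vectors: the union is empty.

    An all-zero orientation image almost always means preprocessing failed,
    so by default this surfaces loudly instead of propagating a NaN.
    """
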