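"""Exception and warning types shared across the package."""


class MdsInferError(Exception):
    """Base class for all package errors."""


class FormatError(MdsInferError, ValueError):
    """A file or table does not match the expected layout (missing column, bad cell)."""


class ValidationError(MdsInferError, ValueError):
    """An in-memory object violates a structural invariant (asymmetry, label mismatch...)."""


class MissingCellError(MdsInferError, ValueError):
    """A participant lacks trials for some stimulus pair, so no d' can be computed."""


class InsufficientDataError(MdsInferError, ValueError):
    """Too few observations to run the requested statistical test."""


class SelfIntersectionError(ValidationError):
    """An ordered vertex list forms a self-intersecting polygon."""

    def __init__(self, edge_a: int, edge_b: int):
        self.edge_a = edge_a
        self.edge_b = edge_b
        super().__init__(
            f"polygon is self-intersecting: edge {edge_a} crosses edge {edge_b}"
        )


class CollinearityWarning(UserWarning):
    """All points of a group lie on a line; its dispersion area is 0 by construction."""


class NegativeDPrimeWarning(UserWarning):
    """A negative d' was floored at 0 when building a dissimilarity matrix."""


class NegativeEigenvalueWarning(UserWarning):
    """The dissimilarity matrix is strongly non-Euclidean (large negative eigenvalue)."""
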