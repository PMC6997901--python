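"""Classical (Torgerson/Gower) multidimensional scaling, per participant.

Classical MDS, a.k.a. principal coordinate analysis, embeds n objects in a
k-dimensional Cartesian space so that pairwise Euclidean distances between
the embedded points approximate the input dissimilarities: the squared
dissimilarity matrix is double-centered, B = -1/2 J (D o D) J, and the top-k
eigenpairs of B give the coordinates (eigenvector columns scaled by the
square root of their eigenvalue).  When D is itself Euclidean and embeddable
in k dimensions the reconstruction is exact.

Two aggregation pipelines are provided for a multi-participant study:

* ``per_participant_solutions`` + ``average_coordinates`` — one MDS solution
  per participant, statistics computed per participant, the element-wise mean
  of coordinates used only for plotting;
* ``grand_mean_solution`` — the conventional alternative: average the
  dissimilarity matrices first, then run a single MDS.

Per-participant solutions are unique only up to rotation/reflection, so raw
coordinate averaging can distort the mean configuration; ``align="procrustes"``
rigidly aligns every solution to the first before averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform

from .exceptions import NegativeEigenvalueWarning, ValidationError
from .trials import DissimilarityMatrix

Align = Literal["none", "procrustes"]

GRAND_MEAN_ID = "grand_mean"


@dataclass(frozen=True)
class MDSSolution:
    """One participant's classical-MDS embedding.

    Attributes
    ----------
    participant_id
        Participant label, or ``"grand_mean"`` for the pooled solution.
    labels
        Object labels, row-aligned with ``coordinates``.
    coordinates
        n x k array of object coordinates (perceptual units).  Columns whose
        eigenvalue is non-positive are zero-filled.
    eigenvalues
        The k largest eigenvalues of the double-centered matrix, descending.
    n_negative_eigenvalues
        How many of all n eigenvalues are negative — a diagnostic for
        non-Euclidean input (d' matrices need not satisfy the Euclidean
        four-point condition).
    negative_share
        |most negative eigenvalue| / largest positive eigenvalue (0 when the
        input is Euclidean); a crude severity measure for the same diagnostic.
    """

    participant_id: str
    labels: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    n_negative_eigenvalues: int
    negative_share: float

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def point(self, label: str) -> np.ndarray:
        return self.coordinates[self.labels.index(label)]

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distances among the embedded objects (n x n)."""
        return squareform(pdist(self.coordinates))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.k)]
        df = pd.DataFrame(self.coordinates, columns=cols)
        df.insert(0, "label", list(self.labels))
        df.insert(0, "participant", self.participant_id)
        return df


def double_center(D: DissimilarityMatrix | np.ndarray) -> np.ndarray:
    """Gower's double-centered matrix B = -1/2 J (D o D) J.

    J = I - 11'/n is the centering projector; every row and column of B sums
    to zero and B is symmetric.
    """
    values = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    A = -0.5 * values**2
    row_mean = A.mean(axis=1, keepdims=True)
    col_mean = A.mean(axis=0, keepdims=True)
    return A - row_mean - col_mean + A.mean()


def _fix_column_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: each column's largest-|entry| is positive."""
    if coords.size == 0:
        return coords
    anchor = np.abs(coords).argmax(axis=-2, keepdims=True)
    sign = np.sign(np.take_along_axis(coords, anchor, axis=-2))
    sign[sign == 0] = 1.0
    return coords * sign


def embed_batch(D_stack: np.ndarray, k: int = 2):
    """Classical-MDS coordinates for a stack of dissimilarity matrices.

    Parameters
    ----------
    D_stack
        Array of shape (m, n, n) — m symmetric zero-diagonal matrices.
    k
        Embedding dimensionality, 1 <= k <= n-1.

    Returns
    -------
    coords : (m, n, k) array
    eigenvalues : (m, k) array, descending per matrix
    n_negative : (m,) int array — negative eigenvalues per matrix
    negative_share : (m,) array — |min eigenvalue| / max eigenvalue (0 if none)

    This is the vectorised work-horse behind :func:`classical_mds`; large
    simulation studies call it directly to avoid per-matrix overhead.
    """
    D_stack = np.asarray(D_stack, dtype=float)
    if D_stack.ndim == 2:
        D_stack = D_stack[None]
    m, n, n2 = D_stack.shape
    if n != n2:
        raise ValidationError(f"matrices must be square, got {D_stack.shape}")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {k}")

    A = -0.5 * D_stack**2
    B = (
        A
        - A.mean(axis=-1, keepdims=True)
        - A.mean(axis=-2, keepdims=True)
        + A.mean(axis=(-2, -1), keepdims=True)
    )
    eigval, eigvec = np.linalg.eigh(B)  # ascending
    eigval = eigval[..., ::-1]
    eigvec = eigvec[..., ::-1]

    tol = np.maximum(np.abs(eigval).max(axis=-1, keepdims=True), 1.0) * 1e-12
    n_negative = (eigval < -tol).sum(axis=-1)
    max_pos = np.maximum(eigval[..., 0], 0.0)
    most_neg = np.minimum(eigval[..., -1], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        negative_share = np.where(max_pos > 0, -most_neg / max_pos, 0.0)

    top = eigval[..., :k]
    scale = np.sqrt(np.maximum(top, 0.0))  # zero-fill non-positive dimensions
    coords = _fix_column_signs(eigvec[..., :k] * scale[..., None, :])
    return coords, top, n_negative.astype(int), negative_share


def classical_mds(
    D: DissimilarityMatrix,
    k: int = 2,
    participant_id: str | None = None,
) -> MDSSolution:
    """Classical MDS (PCoA) of one dissimilarity matrix.

    Coordinates for dimensions with non-positive eigenvalues are zero-filled
    and counted in ``n_negative_eigenvalues``; a warning is raised when the
    most negative eigenvalue exceeds 10% of the largest positive one (a
    strongly non-Euclidean input).  Column signs follow the convention that
    the largest-magnitude entry of each column is positive, so output is
    deterministic across runs.
    """
    coords, eigvals, n_neg, neg_share = embed_batch(D.values[None], k=k)
    share = float(neg_share[0])
    if share > 0.1:
        warnings.warn(
            f"dissimilarity matrix is strongly non-Euclidean: |most negative "
            f"eigenvalue| is {share:.1%} of the largest positive one",
            NegativeEigenvalueWarning,
        )
    return MDSSolution(
        participant_id=participant_id if participant_id is not None else "",
        labels=D.labels,
        coordinates=coords[0],
        eigenvalues=eigvals[0],
        n_negative_eigenvalues=int(n_neg[0]),
        negative_share=share,
    )


def per_participant_solutions(
    matrices: Mapping[str, DissimilarityMatrix] | Iterable[DissimilarityMatrix],
    k: int = 2,
) -> list[MDSSolution]:
    """One MDS solution per participant; all matrices must share label order."""
    if isinstance(matrices, Mapping):
        items = list(matrices.items())
    else:
        items = [(getattr(m, "participant_id", str(i)), m) for i, m in enumerate(matrices)]
    if not items:
        raise ValidationError("no dissimilarity matrices supplied")
    labels = items[0][1].labels
    for pid, m in items:
        if m.labels != labels:
            raise ValidationError(
                f"participant {pid!r} labels {m.labels} != {labels}"
            )
    return [classical_mds(m, k=k, participant_id=pid) for pid, m in items]


def apply_random_rigid_motions(
    solutions: Sequence[MDSSolution], seed: int = 0
) -> list[MDSSolution]:
    """Re-orient each solution by a random rotation/reflection (and shift).

    Any rigid motion of an MDS solution reproduces the input dissimilarities
    equally well — the orientation of each participant's solution is
    arbitrary.  This helper makes that arbitrariness explicit, e.g. to
    demonstrate that per-participant distances and areas are unaffected while
    naive coordinate averaging is not.
    """
    rng = np.random.default_rng(seed)
    out = []
    for sol in solutions:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        Q = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        if rng.random() < 0.5:
            Q = Q @ np.diag([1.0, -1.0])
        k = sol.coordinates.shape[1]
        if k != 2:
            raise ValidationError("random rigid motions implemented for k = 2 only")
        coords = sol.coordinates @ Q + rng.uniform(-1.0, 1.0, size=2)
        out.append(
            MDSSolution(
                participant_id=sol.participant_id,
                labels=sol.labels,
                coordinates=coords,
                eigenvalues=sol.eigenvalues,
                n_negative_eigenvalues=sol.n_negative_eigenvalues,
                negative_share=sol.negative_share,
            )
        )
    return out


def procrustes_align(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigidly align X to reference: translate, then rotate/reflect (no scaling)."""
    X = np.asarray(X, float)
    reference = np.asarray(reference, float)
    Xc = X - X.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    R, _ = orthogonal_procrustes(Xc, ref_c)
    return Xc @ R + reference.mean(axis=0)


@dataclass(frozen=True)
class AggregateConfiguration:
    """Mean object coordinates across participants, for plotting.

    ``method`` records which pipeline produced it: ``"average_coordinates"``
    (mean of per-participant MDS coordinates) or ``"grand_mean_dissimilarity"``
    (single MDS of the averaged matrix).  ``per_participant_coordinates``
    stores the (possibly Procrustes-aligned) matrices that were averaged.
    """

    labels: tuple[str, ...]
    mean_coordinates: np.ndarray
    per_participant_coordinates: tuple[np.ndarray, ...]
    participant_ids: tuple[str, ...]
    method: str
    align: Align = "none"

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.mean_coordinates.shape[1])]
        df = pd.DataFrame(self.mean_coordinates, columns=cols)
        df.insert(0, "label", list(self.labels))
        return df


def average_coordinates(
    solutions: Sequence[MDSSolution], align: Align = "none"
) -> AggregateConfiguration:
    """Element-wise mean of per-participant coordinates.

    With ``align="none"`` (the default) raw coordinates are averaged exactly
    as produced — faithful to the common practice, but not rotation-safe:
    mirror-image solutions cancel.  With ``align="procrustes"`` every solution
    is first rigidly aligned to the first one.
    """
    if not solutions:
        raise ValidationError("no solutions to average")
    labels = solutions[0].labels
    for s in solutions[1:]:
        if s.labels != labels:
            raise ValidationError("solutions have mismatched labels")
    mats = [s.coordinates for s in solutions]
    if align == "procrustes":
        ref = mats[0]
        mats = [ref] + [procrustes_align(m, ref) for m in mats[1:]]
    elif align != "none":
        raise ValueError(f"unknown align option {align!r}")
    return AggregateConfiguration(
        labels=labels,
        mean_coordinates=np.mean(mats, axis=0),
        per_participant_coordinates=tuple(mats),
        participant_ids=tuple(s.participant_id for s in solutions),
        method="average_coordinates",
        align=align,
    )


def grand_mean_solution(
    matrices: Mapping[str, DissimilarityMatrix] | Iterable[DissimilarityMatrix],
    k: int = 2,
) -> MDSSolution:
    """The conventional pipeline: average the matrices, then one MDS solution."""
    from .sensitivity import grand_mean_matrix

    mats = list(matrices.values()) if isinstance(matrices, Mapping) else list(matrices)
    return classical_mds(grand_mean_matrix(mats), k=k, participant_id=GRAND_MEAN_ID)
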