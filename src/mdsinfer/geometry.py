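"""Distances and shoelace dispersion areas in the perceptual space.

The two statistics of interest, computed per participant on that
participant's own MDS coordinates:

* the Euclidean distance between two objects (perceptual units, p.u.);
* the area of the simple polygon spanned by a group of >= 3 objects — the
  surveyor's (shoelace) formula — as an operationalisation of how dispersed
  the group is (p.u. squared).

The shoelace formula requires the vertices in boundary order (clockwise or
counterclockwise) and a non-self-intersecting polygon; ``order_vertices``
automates the ordering by angular sort about the centroid and
``is_simple_polygon`` verifies the result.  If all points of a group are
collinear the area is 0 no matter how spread out they are — an inherent
limitation of an area-based dispersion measure, reported as a warning rather
than an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import CollinearityWarning, SelfIntersectionError, ValidationError
from .pcoa import MDSSolution

Kind = Literal["distance", "area"]

#: Relative tolerance for declaring a point set collinear: the largest
#: triangle among the points has area below COLLINEAR_RTOL * diameter**2.
COLLINEAR_RTOL = 1e-12


@dataclass(frozen=True)
class GeometryStat:
    """One participant's distance (p.u.) or polygon area (p.u.^2).

    ``members`` holds the object labels in the order actually used — for an
    area this is the vertex order the shoelace formula walked, which can
    legitimately differ between participants.
    """

    participant_id: str
    kind: Kind
    members: tuple[str, ...]
    value: float

    def __post_init__(self):
        if self.kind == "distance" and len(self.members) != 2:
            raise ValidationError("a distance involves exactly 2 objects")
        if self.kind == "area" and len(self.members) < 3:
            raise ValidationError("an area involves at least 3 objects")
        if self.value < 0:
            raise ValidationError("distances and areas are non-negative")


def distance(p1, p2) -> float | np.ndarray:
    """Euclidean distance sqrt((x2-x1)^2 + (y2-y1)^2); broadcasts over (..., 2)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = np.sqrt(((p2 - p1) ** 2).sum(axis=-1))
    return float(d) if d.ndim == 0 else d


def triangle_area(p1, p2, p3) -> float | np.ndarray:
    """Shoelace area of a triangle |x1 y2 - y1 x2 + x2 y3 - y2 x3 + x3 y1 - y3 x1| / 2.

    Invariant under any permutation of the three points and always
    non-negative.  Broadcasts over leading axes of (..., 2) inputs.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    x1, y1 = p1[..., 0], p1[..., 1]
    x2, y2 = p2[..., 0], p2[..., 1]
    x3, y3 = p3[..., 0], p3[..., 1]
    a = np.abs(x1 * y2 - y1 * x2 + x2 * y3 - y2 * x3 + x3 * y1 - y3 * x1) / 2.0
    return float(a) if a.ndim == 0 else a


def polygon_area(vertices, check: bool = True) -> float:
    """Shoelace area of a simple polygon from its ordered vertices (n >= 3).

    Walk the vertices clockwise or counterclockwise; the starting vertex and
    the direction do not change the result (absolute value).  With
    ``check=True`` (default) the vertex order is validated: self-intersecting
    input raises :class:`SelfIntersectionError` naming the crossing edges.
    Collinear vertex sets return 0 with a :class:`CollinearityWarning`.
    """
    V = np.asarray(vertices, dtype=float)
    if V.ndim != 2 or V.shape[1] != 2 or V.shape[0] < 3:
        raise ValidationError(f"need an (n>=3, 2) vertex array, got shape {V.shape}")
    if is_collinear(V):
        warnings.warn(
            "all polygon vertices are collinear; area is 0 regardless of spread",
            CollinearityWarning,
        )
        return 0.0
    if check:
        crossing = _find_crossing(V)
        if crossing is not None:
            raise SelfIntersectionError(*crossing)
    x, y = V[:, 0], V[:, 1]
    return float(np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def is_collinear(points) -> bool:
    """True when every triangle among the points is degenerate (relative tol)."""
    P = np.asarray(points, dtype=float)
    if len(P) < 3:
        return True
    diam2 = max(((P[None] - P[:, None]) ** 2).sum(axis=-1).max(), np.finfo(float).tiny)
    max_area = max(
        triangle_area(P[i], P[j], P[k]) for i, j, k in combinations(range(len(P)), 3)
    )
    return max_area < COLLINEAR_RTOL * diam2


def _orient(a, b, c) -> float:
    return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])


def _on_segment(a, b, p) -> bool:
    return (
        min(a[0], b[0]) <= p[0] <= max(a[0], b[0])
        and min(a[1], b[1]) <= p[1] <= max(a[1], b[1])
    )


def _segments_intersect(a, b, c, d) -> bool:
    """Closed-segment intersection test (includes touching and collinear overlap)."""
    o1, o2 = _orient(a, b, c), _orient(a, b, d)
    o3, o4 = _orient(c, d, a), _orient(c, d, b)
    if (o1 > 0) != (o2 > 0) and (o3 > 0) != (o4 > 0) and 0 not in (o1, o2, o3, o4):
        return True
    for (u, v, p) in ((a, b, c), (a, b, d), (c, d, a), (c, d, b)):
        if _orient(u, v, p) == 0 and _on_segment(u, v, p):
            return True
    return False


def _find_crossing(vertices: np.ndarray) -> tuple[int, int] | None:
    """First pair of non-adjacent edges that intersect, or None (O(n^2))."""
    n = len(vertices)
    edges = [(vertices[i], vertices[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            adjacent = (j == i + 1) or (i == 0 and j == n - 1)
            if adjacent:
                continue
            if _segments_intersect(*edges[i], *edges[j]):
                return i, j
    return None


def is_simple_polygon(vertices) -> bool:
    """True iff no two non-adjacent edges of the closed polygon intersect."""
    V = np.asarray(vertices, dtype=float)
    if V.ndim != 2 or V.shape[1] != 2 or V.shape[0] < 3:
        raise ValidationError(f"need an (n>=3, 2) vertex array, got shape {V.shape}")
    return _find_crossing(V) is None


def vertex_order(points) -> np.ndarray:
    """Boundary ordering of a point set: angular sort about the centroid.

    Returns index array ``idx`` such that ``points[idx]`` walks the points
    counterclockwise around their centroid; ties in angle are broken by
    distance from the centroid.  For star-shaped point sets (every
    configuration seen in practice at n <= ~8) the result is a simple polygon.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2 or P.shape[0] < 3:
        raise ValidationError(f"need an (n>=3, 2) point array, got shape {P.shape}")
    centred = P - P.mean(axis=0)
    angles = np.arctan2(centred[:, 1], centred[:, 0])
    radii = np.hypot(centred[:, 0], centred[:, 1])
    return np.lexsort((radii, angles))


def order_vertices(points) -> np.ndarray:
    """The points reordered by :func:`vertex_order` (simple-polygon order)."""
    P = np.asarray(points, dtype=float)
    return P[vertex_order(P)]


def group_area(points, labels: Sequence[str] | None = None):
    """Dispersion area of an unordered point group (auto-ordered shoelace).

    Triangles need no ordering; larger groups are angularly ordered first and
    the ordering is validated with the segment-intersection test.  Returns
    ``(area, ordered_labels)``; collinear groups give area 0 with a warning.
    """
    P = np.asarray(points, dtype=float)
    n = len(P)
    labels = tuple(labels) if labels is not None else tuple(str(i) for i in range(n))
    if n == 3:
        if is_collinear(P):
            warnings.warn(
                "group is collinear; dispersion area is 0 regardless of spread",
                CollinearityWarning,
            )
            return 0.0, labels
        return float(triangle_area(*P)), labels
    idx = vertex_order(P)
    ordered_labels = tuple(labels[i] for i in idx)
    return polygon_area(P[idx], check=True), ordered_labels


def per_participant_stats(
    solutions: Sequence[MDSSolution],
    members: Sequence[str],
    kind: Kind | None = None,
) -> list[GeometryStat]:
    """One GeometryStat per participant for a distance or area specification.

    ``kind`` defaults to ``"distance"`` for 2 members and ``"area"``
    otherwise.  For areas the vertex ordering is recomputed per participant —
    each participant's configuration differs, so the boundary order can too.
    """
    members = tuple(members)
    if kind is None:
        kind = "distance" if len(members) == 2 else "area"
    if kind == "distance" and len(members) != 2:
        raise ValidationError("distance spec needs exactly 2 members")
    if kind == "area" and len(members) < 3:
        raise ValidationError("area spec needs at least 3 members")

    stats = []
    for sol in solutions:
        unknown = [m for m in members if m not in sol.labels]
        if unknown:
            raise ValidationError(
                f"label(s) {unknown} not in solution for {sol.participant_id!r}"
            )
        pts = np.array([sol.point(m) for m in members])
        if kind == "distance":
            stats.append(
                GeometryStat(sol.participant_id, "distance", members, distance(*pts))
            )
        else:
            area, ordered = group_area(pts, members)
            stats.append(GeometryStat(sol.participant_id, "area", ordered, area))
    return stats


def stats_to_frame(stats: Sequence[GeometryStat]) -> pd.DataFrame:
    """Tidy per-participant statistics table (participant, kind, members, value)."""
    return pd.DataFrame(
        {
            "participant": [s.participant_id for s in stats],
            "kind": [s.kind for s in stats],
            "members": ["-".join(s.members) for s in stats],
            "value": [s.value for s in stats],
        }
    )
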