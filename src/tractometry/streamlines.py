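"""Streamline geometry, distances, clustering and centroid selection.

A streamline is an ordered polyline of 3D points in world millimetres.  All
pairwise comparisons use the minimum average direct-flip (MDF) distance on
arc-length resampled copies with a matched point count, so that the distance
is invariant to traversal orientation and to the tractography step size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

__all__ = [
    "Streamline",
    "ResampledStreamline",
    "Cluster",
    "Tractogram",
    "resample_streamline",
    "mdf_distance",
    "streamline_length",
    "mean_curvature",
    "cluster_streamlines",
    "select_centroid",
]

DEFAULT_RESAMPLE_POINTS = 20


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must be an (n, 3) array, got shape {pts.shape}")
    return pts


@dataclass(frozen=True)
class Streamline:
    """An ordered 3D polyline in world mm with an opaque identifier."""

    points: np.ndarray
    id: Hashable = None

    def __post_init__(self):
        pts = _as_points(self.points)
        if len(pts) < 2:
            raise ValueError(f"streamline {self.id!r}: needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"streamline {self.id!r}: non-finite coordinates")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError(f"streamline {self.id!r}: repeated consecutive points")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ResampledStreamline:
    """A streamline resampled to exactly ``k`` equidistant-arc-length points."""

    points: np.ndarray
    source_id: Hashable = None

    def __post_init__(self):
        object.__setattr__(self, "points", _as_points(self.points))

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Cluster:
    """A group of streamline ids sharing one (roi_a, roi_b) endpoint label."""

    member_ids: list
    label: tuple | None = None

    def __post_init__(self):
        if not self.member_ids:
            raise ValueError("cluster must be nonempty")


@dataclass
class Tractogram:
    """A collection of streamlines in a named template space."""

    streamlines: list[Streamline]
    space: str = "synthetic"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        if not self.space:
            raise ValueError("space tag must be nonempty")
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("voxel-to-world transform must be invertible")

    def __len__(self) -> int:
        return len(self.streamlines)


def _arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_streamline(s: Streamline | ResampledStreamline, k: int) -> ResampledStreamline:
    """Resample to ``k`` points at equal arc-length spacing.

    Endpoints are preserved exactly; interior points are linear interpolants
    along the polyline, so total length is preserved to within ~1% for
    reasonably smooth curves once k >= 20.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pts = np.asarray(s.points, dtype=float)
    cum = _arclength(pts)
    total = cum[-1]
    sid = getattr(s, "id", None) or getattr(s, "source_id", None)
    if total <= 0:
        raise ValueError(f"streamline {sid!r} has zero length; cannot resample")
    target = np.linspace(0.0, total, k)
    out = np.column_stack([np.interp(target, cum, pts[:, i]) for i in range(3)])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return ResampledStreamline(points=out, source_id=sid)


def mdf_distance(a: ResampledStreamline | np.ndarray, b: ResampledStreamline | np.ndarray) -> float:
    """Minimum average direct-flip distance between two matched polylines.

    The mean pointwise Euclidean distance is computed in the given order and
    with one curve reversed; the smaller of the two is returned.  Zero iff
    the curves are identical up to an orientation flip.
    """
    pa = np.asarray(getattr(a, "points", a), dtype=float)
    pb = np.asarray(getattr(b, "points", b), dtype=float)
    if pa.shape != pb.shape:
        raise ValueError(f"point counts differ: {pa.shape[0]} vs {pb.shape[0]}")
    # sort before averaging so the value is exactly symmetric in (a, b)
    # and exactly invariant under flipping either argument
    direct = np.sort(np.linalg.norm(pa - pb, axis=1)).mean()
    flipped = np.sort(np.linalg.norm(pa - pb[::-1], axis=1)).mean()
    return float(min(direct, flipped))


def streamline_length(s: Streamline | ResampledStreamline | np.ndarray) -> float:
    """Polyline length: sum of consecutive-point Euclidean distances (mm)."""
    pts = np.asarray(getattr(s, "points", s), dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def mean_curvature(s: ResampledStreamline | np.ndarray) -> float:
    """Mean discrete curvature (1/mm) over interior points.

    Uses Menger (circumscribed-circle) curvature of consecutive point
    triples: kappa = 4 * area(p0, p1, p2) / (|p0p1| |p1p2| |p0p2|), which is
    robust on arc-length resampled curves and invariant to orientation.
    Collinear triples contribute zero.
    """
    pts = np.asarray(getattr(s, "points", s), dtype=float)
    if len(pts) < 3:
        raise ValueError("mean_curvature requires at least 3 points")
    p0, p1, p2 = pts[:-2], pts[1:-1], pts[2:]
    a = np.linalg.norm(p1 - p0, axis=1)
    b = np.linalg.norm(p2 - p1, axis=1)
    c = np.linalg.norm(p2 - p0, axis=1)
    cross = np.cross(p1 - p0, p2 - p0)
    area2 = np.linalg.norm(cross, axis=1)  # twice the triangle area
    denom = a * b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * area2 / denom, 0.0)
    return float(kappa.mean())


def cluster_streamlines(
    group: Sequence[ResampledStreamline], threshold: float
) -> list[Cluster]:
    """Greedy threshold clustering of resampled streamlines.

    Streamlines are visited in order sorted by ``source_id`` (falling back to
    positional index) so the result is permutation-deterministic.  Each
    streamline joins the first existing cluster whose running centroid (the
    orientation-consistent mean of member polylines) lies within ``threshold``
    MDF; otherwise it founds a new cluster.  Clusters are returned in
    founding order.
    """
    if len(group) == 0:
        raise ValueError("cannot cluster an empty group")
    if threshold <= 0:
        raise ValueError("threshold must be positive")

    def sort_key(item):
        idx, s = item
        sid = s.source_id
        return (0, str(sid), idx) if sid is not None else (1, "", idx)

    ordered = sorted(enumerate(group), key=sort_key)

    centroids: list[np.ndarray] = []  # running mean polylines
    counts: list[int] = []
    members: list[list] = []
    for idx, s in ordered:
        pts = s.points
        sid = s.source_id if s.source_id is not None else idx
        assigned = False
        for ci, cen in enumerate(centroids):
            d_direct = np.linalg.norm(pts - cen, axis=1).mean()
            d_flip = np.linalg.norm(pts[::-1] - cen, axis=1).mean()
            if min(d_direct, d_flip) <= threshold:
                aligned = pts if d_direct <= d_flip else pts[::-1]
                n = counts[ci]
                centroids[ci] = (cen * n + aligned) / (n + 1)
                counts[ci] = n + 1
                members[ci].append(sid)
                assigned = True
                break
        if not assigned:
            centroids.append(pts.copy())
            counts.append(1)
            members.append([sid])
    return [Cluster(member_ids=m) for m in members]


def select_centroid(
    c: Cluster, members: dict | Sequence[ResampledStreamline]
) -> ResampledStreamline:
    """Return the member with the smallest median MDF distance to the others.

    This is the representative-pathway rule used for atlas construction: the
    centroid fiber of a cluster is the member minimizing the median of its
    MDF distances to every other member.  Ties break toward the member
    listed first in ``c.member_ids``.
    """
    if isinstance(members, dict):
        try:
            resolved = [members[i] for i in c.member_ids]
        except KeyError as e:
            raise KeyError(f"unresolvable member id {e.args[0]!r}") from None
    else:
        pool = {s.source_id: s for s in members}
        missing = [i for i in c.member_ids if i not in pool]
        if missing:
            raise KeyError(f"unresolvable member id {missing[0]!r}")
        resolved = [pool[i] for i in c.member_ids]

    n = len(resolved)
    if n == 1:
        return resolved[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = mdf_distance(resolved[i], resolved[j])
    best_i, best_med = 0, np.inf
    for i in range(n):
        med = float(np.median(np.delete(D[i], i)))
        if med < best_med:
            best_i, best_med = i, med
    return resolved[best_i]
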