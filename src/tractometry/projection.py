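"""Sub-voxel projection of scalar volumes onto atlas centroid pathways.

For each point of a centroid polyline, a disc in the plane perpendicular to
the local tangent is searched for the maximum trilinearly interpolated
value of the subject's scalar volume (a TBSS-style perpendicular search).
The location of the maximum — the tract center — is recorded so that other
volumes of the same subject can be sampled at exactly the co-located
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .streamlines import ResampledStreamline

__all__ = [
    "ScalarVolume",
    "TractProfile",
    "sample_trilinear",
    "local_tract_direction",
    "project_scalar",
    "extract_colocated",
]


@dataclass
class ScalarVolume:
    """A 3D scalar grid with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space: str = "template"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        self._inv = np.linalg.inv(self.affine)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self._inv[:3, :3].T + self._inv[:3, 3]


@dataclass
class TractProfile:
    """Along-tract values with the world coordinates where each was found."""

    pathway_id: object
    values: np.ndarray
    centers: np.ndarray
    mask: np.ndarray  # True where the entry is valid
    space: str = "template"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.values)


def _sample(v: ScalarVolume, points: np.ndarray):
    """Trilinear samples at world points; returns (values, inside_mask)."""
    vox = v.world_to_voxel(points)
    shape = np.array(v.data.shape)
    inside = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
    vals = map_coordinates(v.data, vox.T, order=1, mode="nearest")
    vals = np.where(inside, vals, np.nan)
    return vals, inside


def sample_trilinear(v: ScalarVolume, point) -> float:
    """Trilinear interpolation at one world point; NaN if out of bounds."""
    vals, _ = _sample(v, np.atleast_2d(point))
    return float(vals[0])


def local_tract_direction(c: ResampledStreamline | np.ndarray, index: int) -> np.ndarray:
    """Unit tangent at a polyline point (central difference at interior)."""
    pts = np.asarray(getattr(c, "points", c), dtype=float)
    n = len(pts)
    if index < 0 or index >= n:
        raise IndexError(f"index {index} out of range for {n} points")
    if index == 0:
        d = pts[1] - pts[0]
    elif index == n - 1:
        d = pts[-1] - pts[-2]
    else:
        d = pts[index + 1] - pts[index - 1]
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("degenerate tangent")
    return d / norm


def _perp_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the plane perpendicular to tangent."""
    t = tangent / np.linalg.norm(tangent)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(t)))] = 1.0
    e1 = np.cross(t, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    return e1, e2


def _disc_offsets(radius: float, step: float) -> np.ndarray:
    """Polar-grid (u, v) offsets covering a filled disc, center first.

    Ring radii advance by ``step``; each ring is sampled at an angular pitch
    giving ~``step`` arc spacing.  Enumeration order (radius-major, then
    angle) is fixed, which makes the max tie-break deterministic.
    """
    offsets = [(0.0, 0.0)]
    r = step
    while r <= radius + 1e-9:
        n_ang = max(8, int(np.ceil(2 * np.pi * r / step)))
        ang = 2 * np.pi * np.arange(n_ang) / n_ang
        offsets.extend(zip(r * np.cos(ang), r * np.sin(ang)))
        r += step
    return np.asarray(offsets)


def project_scalar(
    v: ScalarVolume,
    c: ResampledStreamline,
    radius: float = 4.0,
    step: float = 0.1,
    pathway_id=None,
) -> TractProfile:
    """Project a scalar volume onto a centroid by perpendicular max search.

    At each centroid point the filled perpendicular disc (``radius`` mm,
    ``step`` mm polar grid) is sampled by trilinear interpolation; the
    maximum value and its world location are recorded.  Equal maxima break
    toward the candidate nearest the centroid point (the grid enumerates
    candidates in increasing ring radius).  Points whose entire disc falls
    outside the volume are masked.
    """
    pts = np.asarray(c.points, dtype=float)
    disc = _disc_offsets(radius, step)
    dist2 = disc[:, 0] ** 2 + disc[:, 1] ** 2

    n = len(pts)
    values = np.full(n, np.nan)
    centers = np.array(pts, dtype=float, copy=True)
    mask = np.zeros(n, dtype=bool)
    for i in range(n):
        tangent = local_tract_direction(c, i)
        e1, e2 = _perp_basis(tangent)
        cand = pts[i] + disc[:, :1] * e1 + disc[:, 1:2] * e2
        vals, inside = _sample(v, cand)
        if not inside.any():
            continue
        vmax = np.nanmax(vals)
        # ties: smallest offset distance wins, then grid order
        tied = np.flatnonzero(np.where(inside, vals, -np.inf) >= vmax - 1e-12)
        best = tied[np.argmin(dist2[tied])]
        values[i] = vals[best]
        centers[i] = cand[best]
        mask[i] = True
    return TractProfile(
        pathway_id=pathway_id if pathway_id is not None else c.source_id,
        values=values,
        centers=centers,
        mask=mask,
        space=v.space,
    )


def extract_colocated(v2: ScalarVolume, profile: TractProfile) -> TractProfile:
    """Sample another same-space volume at a profile's recorded centers."""
    if v2.space != profile.space:
        raise ValueError(
            f"space mismatch: volume {v2.space!r} vs profile {profile.space!r}"
        )
    vals, inside = _sample(v2, profile.centers)
    mask = profile.mask & inside
    vals = np.where(mask, vals, np.nan)
    return TractProfile(
        pathway_id=profile.pathway_id,
        values=vals,
        centers=profile.centers,
        mask=mask,
        space=v2.space,
    )
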