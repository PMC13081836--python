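"""Parcellation anchoring, reliability QC and pathway-atlas assembly.

Streamline endpoints are snapped to the nearest labeled surface vertex to
assign each fiber an unordered ROI pair; ROI-pair fiber-count reliability
(test-retest ICC) drives pre-clustering QC, and per-centroid profile
reliability drives post-clustering QC.  The surviving cluster centroids,
annotated with ROI-pair and functional-network-pair labels, form the
pathway atlas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .streamlines import ResampledStreamline, Tractogram

__all__ = [
    "Parcellation",
    "LabeledSurface",
    "AtlasEntry",
    "PathwayAtlas",
    "snap_endpoints",
    "group_by_roi_pair",
    "icc",
    "merge_parcels",
    "filter_pre_clustering",
    "filter_post_clustering",
    "assemble_atlas",
]


@dataclass
class Parcellation:
    """Region table (id, name, functional-network label) plus adjacency."""

    regions: list[tuple[int, str, str]]
    adjacency: set[frozenset] = field(default_factory=set)

    def __post_init__(self):
        ids = [r[0] for r in self.regions]
        if len(ids) != len(set(ids)):
            raise ValueError("region ids must be unique")
        self._network = {rid: net for rid, _, net in self.regions}
        self._name = {rid: name for rid, name, _ in self.regions}

    def network_of(self, region_id: int) -> str:
        return self._network[region_id]

    def network_pair(self, roi_pair: tuple[int, int]) -> tuple[str, str]:
        a, b = sorted((self._network[roi_pair[0]], self._network[roi_pair[1]]))
        return (a, b)

    def adjacent(self, a: int, b: int) -> bool:
        return frozenset((a, b)) in self.adjacency

    @property
    def region_ids(self) -> list[int]:
        return [r[0] for r in self.regions]


@dataclass
class LabeledSurface:
    """Surface vertex coordinates (mm) with a region label per vertex."""

    vertices: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.labels = np.asarray(self.labels)
        if len(self.vertices) != len(self.labels):
            raise ValueError("vertices and labels must have equal length")
        if len(self.vertices) == 0:
            raise ValueError("surface must be nonempty")


@dataclass
class AtlasEntry:
    centroid: ResampledStreamline
    roi_pair: tuple[int, int]
    network_pair: tuple[str, str]
    n_members: int
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class PathwayAtlas:
    entries: list[AtlasEntry]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def within_network_count(self) -> int:
        return sum(1 for e in self.entries if e.network_pair[0] == e.network_pair[1])

    def between_network_count(self) -> int:
        return len(self.entries) - self.within_network_count()

    def save(self, directory) -> None:
        """Serialize as a directory: centroid TRK plus a JSON sidecar."""
        from .io import write_tractogram
        from .streamlines import Streamline

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tg = Tractogram(
            streamlines=[
                Streamline(points=e.centroid.points, id=str(i))
                for i, e in enumerate(self.entries)
            ],
            space="atlas",
        )
        write_tractogram(tg, directory / "centroids.trk")
        sidecar = {
            "provenance": self.provenance,
            "entries": [
                {
                    "roi_pair": list(e.roi_pair),
                    "network_pair": list(e.network_pair),
                    "n_members": e.n_members,
                    "qc_flags": e.qc_flags,
                }
                for e in self.entries
            ],
        }
        (directory / "atlas.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory) -> "PathwayAtlas":
        from .io import read_tractogram

        directory = Path(directory)
        tg = read_tractogram(directory / "centroids.trk")
        sidecar = json.loads((directory / "atlas.json").read_text())
        entries = [
            AtlasEntry(
                centroid=ResampledStreamline(points=s.points, source_id=str(i)),
                roi_pair=tuple(meta["roi_pair"]),
                network_pair=tuple(meta["network_pair"]),
                n_members=meta["n_members"],
                qc_flags=list(meta["qc_flags"]),
            )
            for i, (s, meta) in enumerate(zip(tg.streamlines, sidecar["entries"]))
        ]
        return cls(entries=entries, provenance=sidecar.get("provenance", {}))


def snap_endpoints(t: Tractogram, surf: LabeledSurface) -> list[tuple]:
    """Assign each streamline the ROI pair of its nearest surface vertices.

    Each endpoint takes the label of the Euclidean-nearest vertex; exact
    distance ties resolve to the lower region id.  ROI pairs are stored
    unordered as (min_id, max_id).
    """
    tree = cKDTree(surf.vertices)
    endpoints = np.array(
        [[s.points[0], s.points[-1]] for s in t.streamlines], dtype=float
    ).reshape(-1, 3)
    k = min(4, len(surf.vertices))
    dist, idx = tree.query(endpoints, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    labels = np.empty(len(endpoints), dtype=surf.labels.dtype)
    for i in range(len(endpoints)):
        tied = idx[i][dist[i] <= dist[i, 0] + 1e-9]
        labels[i] = min(surf.labels[j] for j in tied)
    out = []
    for si, s in enumerate(t.streamlines):
        a, b = labels[2 * si], labels[2 * si + 1]
        lo, hi = (a, b) if a <= b else (b, a)
        out.append((s.id if s.id is not None else si, int(lo), int(hi)))
    return out


def group_by_roi_pair(assignments) -> dict[tuple[int, int], list]:
    """Partition streamline ids by unordered ROI pair."""
    groups: dict[tuple[int, int], list] = {}
    for sid, a, b in assignments:
        key = (a, b) if a <= b else (b, a)
        groups.setdefault(key, []).append(sid)
    return groups


def icc(matrix, variant: str = "two_way") -> float:
    """Test-retest intraclass correlation from ANOVA mean squares.

    Default is the two-way random-effects, single-measurement,
    absolute-agreement form ICC(2,1):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR/MSC/MSE the row (subject), column (visit) and residual mean
    squares of an n x k table.  ``variant="one_way"`` gives ICC(1,1).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n>=2 by k>=2 complete table")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("degenerate input: zero total variance")
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ssr = k * np.sum((row_m - grand) ** 2)
    ssc = n * np.sum((col_m - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if variant == "two_way":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif variant == "one_way":
        msw = (ssc + sse) / (n * (k - 1))
        denom = msr + (k - 1) * msw
        mse = msw
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    if denom == 0:
        raise ValueError("degenerate input: zero denominator")
    return float(np.clip((msr - mse) / denom, -1.0, 1.0))


def _mean_icc(retest_data: dict) -> float:
    vals = []
    for tab in retest_data.values():
        tab = np.asarray(tab, dtype=float)
        grand = tab.mean()
        if np.allclose(tab, grand):
            continue
        vals.append(icc(tab))
    return float(np.mean(vals)) if vals else 0.0


def merge_parcels(
    p: Parcellation,
    count_profiles: dict,
    retest_data: dict,
    corr_min: float = 0.7,
):
    """Merge adjacent same-network parcels with redundant connectivity.

    A candidate pair must be spatially adjacent, share a functional network,
    have Pearson correlation > ``corr_min`` between their fiber-count
    profiles, and the merge (summing their fiber counts) must not reduce the
    mean fiber-count test-retest ICC over all regions.  Candidates are
    visited once, in descending profile correlation; each region merges at
    most once.  Returns the merged parcellation and a log of every decision
    with the four criterion values.
    """
    for rid in p.region_ids:
        if rid not in count_profiles:
            raise KeyError(f"missing count profile for region {rid}")
        if rid not in retest_data:
            raise KeyError(f"missing retest data for region {rid}")

    candidates = []
    for pair in p.adjacency:
        a, b = sorted(pair)
        if a not in count_profiles or b not in count_profiles:
            continue
        pa = np.asarray(count_profiles[a], dtype=float)
        pb = np.asarray(count_profiles[b], dtype=float)
        if pa.std() == 0 or pb.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(pa, pb)[0, 1])
        candidates.append((r, a, b))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    current = {rid: np.asarray(retest_data[rid], dtype=float) for rid in p.region_ids}
    merged_into: dict[int, int] = {}
    log = []
    for r, a, b in candidates:
        same_net = p.network_of(a) == p.network_of(b)
        already = a in merged_into or b in merged_into
        entry = {
            "pair": (a, b),
            "adjacent": True,
            "same_network": same_net,
            "profile_corr": r,
            "icc_before": None,
            "icc_after": None,
            "merged": False,
        }
        if same_net and r > corr_min and not already:
            before = _mean_icc(current)
            trial = {k: v for k, v in current.items() if k not in (a, b)}
            trial[a] = current[a] + current[b]
            after = _mean_icc(trial)
            entry["icc_before"], entry["icc_after"] = before, after
            if after >= before:
                current = trial
                merged_into[b] = a
                entry["merged"] = True
        log.append(entry)

    regions = []
    for rid, name, net in p.regions:
        if rid in merged_into:
            continue
        absorbed = [b for b, a in merged_into.items() if a == rid]
        if absorbed:
            name = name + "+" + "+".join(p._name[b] for b in absorbed)
        regions.append((rid, name, net))
    remap = {b: a for b, a in merged_into.items()}
    adjacency = set()
    for pair in p.adjacency:
        a, b = (remap.get(x, x) for x in sorted(pair))
        if a != b:
            adjacency.add(frozenset((a, b)))
    return Parcellation(regions=regions, adjacency=adjacency), log


def filter_pre_clustering(groups: dict, reliability: dict, icc_min: float = 0.4):
    """Drop ROI-pair fiber groups whose fiber-count ICC is below threshold.

    The criterion is strict: a group is removed iff its ICC < ``icc_min``.
    Returns (retained groups, list of removed pairs).
    """
    missing = [k for k in groups if k not in reliability]
    if missing:
        raise KeyError(f"no reliability entry for group {missing[0]}")
    kept, removed = {}, []
    for key, members in groups.items():
        if reliability[key] < icc_min:
            removed.append(key)
        else:
            kept[key] = members
    return kept, removed


def filter_post_clustering(
    clusters: list,
    centroid_reliability: dict,
    min_size: int = 5,
    icc_min: float = 0.4,
):
    """Drop small clusters and centroids with unreliable scalar profiles.

    ``clusters`` is a list of (cluster_key, size); a cluster survives iff
    size >= min_size and its centroid profile reliability >= icc_min.
    """
    kept, removed = [], []
    for key, size in clusters:
        if key not in centroid_reliability:
            raise KeyError(f"no centroid reliability for cluster {key}")
        if size < min_size or centroid_reliability[key] < icc_min:
            removed.append(key)
        else:
            kept.append((key, size))
    return kept, removed


def assemble_atlas(
    retained,
    parcellation: Parcellation,
    provenance: dict | None = None,
) -> PathwayAtlas:
    """Build the pathway atlas from QC-surviving cluster centroids.

    ``retained`` is a list of (centroid, roi_pair, n_members) triples.
    Network-pair labels derive from the parcellation; each entry is
    classified within- vs between-network by label equality.
    """
    entries = []
    for centroid, roi_pair, n_members in retained:
        a, b = roi_pair
        if a not in parcellation._network or b not in parcellation._network:
            raise KeyError(f"roi pair {roi_pair} absent from parcellation")
        entries.append(
            AtlasEntry(
                centroid=centroid,
                roi_pair=(min(a, b), max(a, b)),
                network_pair=parcellation.network_pair(roi_pair),
                n_members=int(n_members),
            )
        )
    return PathwayAtlas(entries=entries, provenance=provenance or {})
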