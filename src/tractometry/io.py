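"""Readers/writers for tractograms, volumes and tables, plus pipeline config.

Tractograms go through nibabel's streamline API: TRK voxel-order quirks are
normalized by always moving coordinates to world (RAS+ mm) space on load,
so the two dialects round-trip to identical world coordinates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import TckFile, TrkFile
from nibabel.streamlines.tractogram import Tractogram as NibTractogram

from .atlas import LabeledSurface, Parcellation
from .projection import ScalarVolume
from .streamlines import Streamline, Tractogram

__all__ = [
    "PipelineConfig",
    "read_tractogram",
    "write_tractogram",
    "read_volume",
    "write_volume",
    "read_table",
    "read_parcellation",
    "read_surface",
    "profiles_to_table",
]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with validation and a stable hash."""

    resample_points: int = 20
    cluster_threshold_mm: float = 5.0
    icc_min: float = 0.4
    min_cluster_size: int = 5
    # pipeline-scale search; project_scalar's own defaults are 4.0 / 0.1 mm
    search_radius_mm: float = 3.0
    search_step_mm: float = 0.5
    elastic_lambda: float = 0.01
    reference_length_mm: float = 100.0
    n_voxel_pcs: int = 3
    contribution_threshold: float = 0.70
    mad_k: float = 5.0
    alpha: float = 0.05
    n_tests: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.resample_points < 8:
            raise ValueError("resample_points must be >= 8")
        if self.cluster_threshold_mm <= 0:
            raise ValueError("cluster_threshold_mm must be positive")
        if not -1.0 <= self.icc_min <= 1.0:
            raise ValueError("icc_min must be in [-1, 1]")
        if self.search_radius_mm <= 0 or self.search_step_mm <= 0:
            raise ValueError("search radius and step must be positive")
        if not 0.0 < self.contribution_threshold <= 1.0:
            raise ValueError("contribution_threshold must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def read_tractogram(path) -> Tractogram:
    """Read a TRK or TCK file into world-mm streamlines."""
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix == ".trk":
            tf = TrkFile.load(str(path))
        elif suffix == ".tck":
            tf = TckFile.load(str(path))
        else:
            raise ValueError(f"unknown tractogram dialect {suffix!r} (expected .trk/.tck)")
    except (ValueError, KeyError):
        raise
    except Exception as e:  # nibabel raises format-specific errors
        raise ValueError(f"cannot parse {path.name} as a {suffix} tractogram: {e}") from e
    tg = tf.tractogram.to_world()
    streamlines = [
        Streamline(points=np.asarray(pts, dtype=float), id=str(i))
        for i, pts in enumerate(tg.streamlines)
    ]
    return Tractogram(streamlines=streamlines, space="world", affine=np.eye(4))


def write_tractogram(t: Tractogram, path) -> None:
    path = Path(path)
    nt = NibTractogram(
        [np.asarray(s.points, dtype=np.float32) for s in t.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    suffix = path.suffix.lower()
    if suffix == ".trk":
        TrkFile(nt).save(str(path))
    elif suffix == ".tck":
        TckFile(nt).save(str(path))
    else:
        raise ValueError(f"unknown tractogram dialect {suffix!r} (expected .trk/.tck)")


def read_volume(path, space: str = "template") -> ScalarVolume:
    img = nib.load(str(path))
    return ScalarVolume(
        data=np.asanyarray(img.dataobj, dtype=float),
        affine=img.affine,
        space=space,
    )


def write_volume(v: ScalarVolume, path) -> None:
    nib.Nifti1Image(v.data.astype(np.float32), v.affine).to_filename(str(path))


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path.name}: missing required columns {missing}")
    return df


def read_parcellation(path) -> Parcellation:
    """Parcellation TSV: region_id, name, network [, adjacent_to]."""
    df = read_table(path, required=["region_id", "name", "network"])
    regions = [
        (int(r.region_id), str(r.name), str(r.network)) for r in df.itertuples()
    ]
    adjacency = set()
    if "adjacent_to" in df.columns:
        for r in df.itertuples():
            if pd.isna(r.adjacent_to) or r.adjacent_to == "":
                continue
            for other in str(r.adjacent_to).split(";"):
                adjacency.add(frozenset((int(r.region_id), int(other))))
    return Parcellation(regions=regions, adjacency=adjacency)


def read_surface(path) -> LabeledSurface:
    """Surface vertex TSV: x, y, z, region_id."""
    df = read_table(path, required=["x", "y", "z", "region_id"])
    return LabeledSurface(
        vertices=df[["x", "y", "z"]].to_numpy(dtype=float),
        labels=df["region_id"].to_numpy(dtype=int),
    )


def profiles_to_table(profiles: dict) -> pd.DataFrame:
    """Flatten {(subject, pathway) -> TractProfile} into a tidy table."""
    rows = []
    for (subject, pathway), prof in profiles.items():
        for i in range(len(prof)):
            rows.append(
                {
                    "subject": subject,
                    "pathway_id": pathway,
                    "point_index": i,
                    "value": prof.values[i],
                    "x": prof.centers[i, 0],
                    "y": prof.centers[i, 1],
                    "z": prof.centers[i, 2],
                    "masked": not bool(prof.mask[i]),
                }
            )
    return pd.DataFrame(rows)
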