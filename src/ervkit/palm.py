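"""Live-cell PALM cluster metrics for RNA polymerase II.

Localizations accumulated over the acquisition window (100 s by default) are
grouped by density-based clustering; a cluster's size is its total
localization count over that window. Downstream metrics: the distance from a
tagged nascent-transcription site to the nearest cluster center (and that
cluster's size), and per-cell cluster counts and mean sizes.

The clustering radius (50 nm) and minimum point count (10) are declared
package defaults, exposed in every entry point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "LocalizationSet",
    "PalmCluster",
    "SiteAnchor",
    "cluster_localizations",
    "nearest_cluster_to_site",
    "per_cell_summary",
    "read_localizations_csv",
    "write_clusters_csv",
]

DEFAULT_RADIUS_NM = 50.0
DEFAULT_MIN_POINTS = 10


@dataclass
class LocalizationSet:
    """PALM localizations of one cell: columns x (nm), y (nm), t (s)."""

    points: np.ndarray  # (n, 3)
    acquisition_span: float = 100.0  # s
    cell_id: object = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("localization coordinates must be finite")
        t = self.points[:, 2]
        if t.size and (t.min() < 0 or t.max() > self.acquisition_span):
            raise ValueError("timestamps outside [0, acquisition_span]")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class PalmCluster:
    members: Tuple[int, ...]
    size: int
    center: Tuple[float, float]  # nm
    cell_id: object = None


@dataclass(frozen=True)
class SiteAnchor:
    """Center (nm) of the MS2 nascent-transcription signal."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("site anchor coordinates must be finite")


def cluster_localizations(
    locs: LocalizationSet,
    radius: float = DEFAULT_RADIUS_NM,
    min_points: int = DEFAULT_MIN_POINTS,
) -> List[PalmCluster]:
    """Density-based (DBSCAN) clustering of localizations in xy.

    The time coordinate is ignored: cluster size counts all localizations
    across the acquisition window. Points in no dense neighborhood remain
    unclustered noise.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    if len(locs) == 0:
        return []
    from sklearn.cluster import DBSCAN

    xy = locs.points[:, :2]
    labels = DBSCAN(eps=radius, min_samples=min_points).fit(xy).labels_
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        members = np.flatnonzero(labels == lab)
        center = xy[members].mean(axis=0)
        clusters.append(
            PalmCluster(
                members=tuple(int(i) for i in members),
                size=int(members.size),
                center=(float(center[0]), float(center[1])),
                cell_id=locs.cell_id,
            )
        )
    return clusters


def nearest_cluster_to_site(
    site: SiteAnchor, clusters: Sequence[PalmCluster]
) -> Tuple[float, int]:
    """(distance in nm, size) of the cluster whose center is nearest the site."""
    if not clusters:
        raise ValueError("no clusters detected; nearest-cluster distance undefined")
    d = [math.hypot(c.center[0] - site.x, c.center[1] - site.y) for c in clusters]
    i = int(np.argmin(d))
    return float(d[i]), clusters[i].size


def per_cell_summary(clusters_by_cell: Mapping[object, Sequence[PalmCluster]]) -> pd.DataFrame:
    """Cluster count and mean cluster size per cell (mean NaN when no clusters)."""
    rows = []
    for cell_id, clusters in clusters_by_cell.items():
        sizes = [c.size for c in clusters]
        rows.append(
            {
                "cell_id": cell_id,
                "n_clusters": len(sizes),
                "mean_size": float(np.mean(sizes)) if sizes else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "n_clusters", "mean_size"])


def read_localizations_csv(path: str, acquisition_span: float = 100.0) -> List[LocalizationSet]:
    """Read localizations (columns x_nm, y_nm, t_s[, cell_id]) into per-cell sets."""
    df = pd.read_csv(path)
    required = {"x_nm", "y_nm", "t_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if "cell_id" not in df.columns:
        df["cell_id"] = 0
    sets = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        sets.append(
            LocalizationSet(
                points=sub[["x_nm", "y_nm", "t_s"]].to_numpy(),
                acquisition_span=acquisition_span,
                cell_id=cell_id,
            )
        )
    return sets


def write_clusters_csv(clusters: Iterable[PalmCluster], path: str) -> None:
    pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "center_x_nm": c.center[0],
                "center_y_nm": c.center[1],
                "size": c.size,
            }
            for c in clusters
        ],
        columns=["cell_id", "center_x_nm", "center_y_nm", "size"],
    ).to_csv(path, index=False)
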