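"""Pre-clustering of events with similar MCF profiles across biopsies.

Events belonging to the same subclone travel together: their MCFs rise
and fall in lockstep across biopsies.  Grouping such events before the
deconvolution shrinks the search space; it is an optimization only, not
a clonal-inference step, and can be bypassed (every event then forms a
singleton cluster) without changing the result on clean data.

DBSCAN is used with ``min_pts=1`` so no event is ever discarded as
noise — every alteration must reach the event matrix.  Each event is a
point in B-dimensional MCF space (B = number of biopsies).  By default
distances are Euclidean on the raw percentage scale, so the default
radius ``eps=0.5`` groups events whose MCF profiles agree within about
half a percentage point; ``scale="unit"`` divides coordinates by 100
first for data calibrated on a 0-1 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from sklearn.cluster import DBSCAN

from .event_unification import EventCatalog
from .segment_io import McfMatrix

__all__ = [
    "ClusterSet",
    "ClusterSizeMatrix",
    "dbscan_clusters",
    "k_distance_profile",
    "cluster_size_matrix",
    "singleton_clusters",
]

DEFAULT_EPS = 0.5
STEM_CLUSTER_ID = "Stem"


@dataclass
class ClusterSet:
    """Disjoint clusters of event ids; the stem events form one dedicated cluster."""

    clusters: dict[str, list[str]]  # cluster id -> member event ids
    stem_cluster: str | None = None
    noise_events: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for members in self.clusters.values():
            for e in members:
                if e in seen:
                    raise ValueError(f"event {e} assigned to multiple clusters")
                seen.add(e)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.clusters)

    def subclonal_ids(self) -> list[str]:
        return [c for c in self.clusters if c != self.stem_cluster]

    def members(self, cluster_id: str) -> list[str]:
        return self.clusters[cluster_id]

    def cluster_of(self, event_id: str) -> str:
        for cid, members in self.clusters.items():
            if event_id in members:
                return cid
        raise KeyError(event_id)

    def n_events(self) -> int:
        return sum(len(m) for m in self.clusters.values())


@dataclass
class ClusterSizeMatrix:
    """Per-biopsy cluster sizes: mean MCF over member events (percent)."""

    cluster_ids: list[str]
    biopsies: list[str]
    values: np.ndarray  # C x B

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cluster_ids), len(self.biopsies)):
            raise ValueError("size matrix shape mismatch")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 100):
            raise ValueError("cluster sizes must lie in [0, 100]")

    def size(self, cluster_id: str, biopsy: str) -> float:
        return float(
            self.values[self.cluster_ids.index(cluster_id), self.biopsies.index(biopsy)]
        )

    def row(self, cluster_id: str) -> np.ndarray:
        return self.values[self.cluster_ids.index(cluster_id)]


def _coords(T: McfMatrix, scale: str) -> np.ndarray:
    X = np.nan_to_num(T.values, nan=0.0)
    if scale == "unit":
        return X / 100.0
    if scale == "percent":
        return X
    raise ValueError(f"unknown scale {scale!r}")


def dbscan_clusters(
    T: McfMatrix,
    eps: float = DEFAULT_EPS,
    min_pts: int = 1,
    scale: str = "percent",
    catalog: EventCatalog | None = None,
) -> ClusterSet:
    """Cluster subclonal events by MCF-profile proximity.

    ``T`` should be restricted to subclonal events; if a ``catalog`` is
    given, its stem events are split off into the dedicated stem
    cluster first and the remaining rows are clustered.  With
    ``min_pts=1`` every point is a core point, so no event is lost.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    stem_ids: list[str] = []
    sub_ids = list(T.events)
    if catalog is not None:
        stem_ids = [e for e in T.events if catalog.is_stem.get(e, False)]
        sub_ids = [e for e in T.events if e not in set(stem_ids)]

    clusters: dict[str, list[str]] = {}
    stem_cluster = None
    if stem_ids:
        clusters[STEM_CLUSTER_ID] = stem_ids
        stem_cluster = STEM_CLUSTER_ID

    if sub_ids:
        sub = T.subset(sub_ids)
        X = _coords(sub, scale)
        labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(X)
        next_singleton = 0
        by_label: dict[int, list[str]] = {}
        for event, lab in zip(sub_ids, labels):
            by_label.setdefault(int(lab), []).append(event)
        # -1 only possible when min_pts > 1; keep those events as singletons
        noise = by_label.pop(-1, [])
        for i, lab in enumerate(sorted(by_label)):
            clusters[f"C{i + 1}"] = by_label[lab]
        for event in noise:
            next_singleton += 1
            clusters[f"N{next_singleton}"] = [event]
        cs = ClusterSet(clusters=clusters, stem_cluster=stem_cluster, noise_events=noise)
    else:
        cs = ClusterSet(clusters=clusters, stem_cluster=stem_cluster)
    return cs


def singleton_clusters(T: McfMatrix, catalog: EventCatalog | None = None) -> ClusterSet:
    """Bypass pre-clustering: every subclonal event is its own cluster."""
    stem_ids: list[str] = []
    sub_ids = list(T.events)
    if catalog is not None:
        stem_ids = [e for e in T.events if catalog.is_stem.get(e, False)]
        sub_ids = [e for e in T.events if e not in set(stem_ids)]
    clusters: dict[str, list[str]] = {}
    stem_cluster = None
    if stem_ids:
        clusters[STEM_CLUSTER_ID] = stem_ids
        stem_cluster = STEM_CLUSTER_ID
    for i, e in enumerate(sub_ids):
        clusters[f"C{i + 1}"] = [e]
    return ClusterSet(clusters=clusters, stem_cluster=stem_cluster)


def k_distance_profile(T: McfMatrix, k: int = 1, scale: str = "percent") -> np.ndarray:
    """Distance to each event's k-th nearest neighbor, sorted descending.

    The elbow of this profile is the standard heuristic for choosing
    ``eps``; the output has one entry per event.
    """
    X = _coords(T, scale)
    n = X.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} events for k={k}")
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    kth = np.sort(d, axis=1)[:, k - 1]
    return np.sort(kth)[::-1]


def cluster_size_matrix(clusters: ClusterSet, T: McfMatrix) -> ClusterSizeMatrix:
    """Per-biopsy cluster size: arithmetic mean MCF of member events."""
    values = np.zeros((len(clusters.cluster_ids), len(T.biopsies)))
    for i, cid in enumerate(clusters.cluster_ids):
        rows = np.array([T.row(e) for e in clusters.members(cid)], dtype=float)
        rows = np.nan_to_num(rows, nan=0.0)
        values[i] = rows.mean(axis=0)
    return ClusterSizeMatrix(
        cluster_ids=list(clusters.cluster_ids), biopsies=list(T.biopsies), values=values
    )
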