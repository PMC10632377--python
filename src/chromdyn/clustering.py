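"""K-means trajectory clustering of dynamic peaks and archetype annotation.

Dynamic peaks are summarized as condition-mean z-score profiles (one value
per time point) and clustered with best-of-restarts k-means.  Each cluster
centroid is then annotated with a trajectory archetype — early / pan-in-vivo
/ late gain or loss — by comparing the in vivo time points to the in vitro
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .matrix import SampleMatrix, order_conditions

__all__ = [
    "ClusterResult",
    "condition_profiles",
    "kmeans_cluster",
    "annotate_archetype",
    "ARCHETYPE_LABELS",
]

ARCHETYPE_LABELS = (
    "early_gain",
    "pan_gain",
    "late_gain",
    "early_loss",
    "pan_loss",
    "late_loss",
    "complex",
)


@dataclass
class ClusterResult:
    """Labels, centroids and archetype calls for a k-means run.

    ``labels`` maps peak id to a 1-based cluster index; ``centroids`` holds
    the member-mean condition profile per cluster (rows ``1..k``);
    ``archetype`` maps cluster index to a trajectory archetype label.
    """

    labels: pd.Series
    centroids: pd.DataFrame
    k: int
    archetype: dict[int, str]
    seed: int
    inertia: float
    silhouette: float | None = None

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def write(self, labels_path: str | Path, centroids_path: str | Path | None = None) -> None:
        out = pd.DataFrame(
            {
                "cluster": self.labels,
                "archetype": [self.archetype[c] for c in self.labels],
            }
        )
        out.index.name = "peak_id"
        out.to_csv(labels_path, sep="\t")
        if centroids_path is not None:
            cent = self.centroids.copy()
            cent.insert(0, "archetype", [self.archetype[c] for c in cent.index])
            cent.index.name = "cluster"
            cent.to_csv(centroids_path, sep="\t")


def condition_profiles(z: SampleMatrix) -> pd.DataFrame:
    """Collapse a z-scored matrix to per-condition means.

    Returns a peaks × conditions frame with the metastasis time course
    ordered (invitro, early, late) when those labels are present.
    """
    conditions = z.conditions
    counts = conditions.value_counts()
    if (counts < 1).any():
        raise ValueError("every condition must have at least one sample")
    profiles = z.values.T.groupby(conditions).mean().T
    return profiles[order_conditions(conditions)]


def annotate_archetype(
    centroid: Mapping[str, float] | pd.Series,
    delta: float = 0.5,
) -> str:
    """Classify a (invitro, early, late) condition profile.

    A gain/loss is called when the in vivo point differs from in vitro by
    more than ``delta`` z-units; "pan" means both in vivo points move, and
    profiles with no call in either direction are "complex".
    """
    for key in ("invitro", "early", "late"):
        if key not in centroid:
            raise ValueError(f"profile missing condition {key!r}")
    v, e, l = centroid["invitro"], centroid["early"], centroid["late"]
    if e - v > delta and l - v > delta:
        return "pan_gain"
    if e - v > delta:
        return "early_gain"
    if l - v > delta:
        return "late_gain"
    if v - e > delta and v - l > delta:
        return "pan_loss"
    if v - e > delta:
        return "early_loss"
    if v - l > delta:
        return "late_loss"
    return "complex"


def _order_clusters(centroids: pd.DataFrame) -> list[int]:
    """Stable cluster ordering: descending early−invitro, then late−invitro."""
    cols = list(centroids.columns)
    if {"invitro", "early", "late"} <= set(cols):
        key1 = centroids["early"] - centroids["invitro"]
        key2 = centroids["late"] - centroids["invitro"]
    else:
        key1 = centroids[cols[min(1, len(cols) - 1)]] - centroids[cols[0]]
        key2 = centroids[cols[-1]] - centroids[cols[0]]
    order = sorted(
        centroids.index,
        key=lambda c: (-key1.loc[c], -key2.loc[c], c),
    )
    return list(order)


def kmeans_cluster(
    profiles: pd.DataFrame,
    k: int = 8,
    seed: int = 0,
    n_init: int = 50,
    delta: float = 0.5,
    compute_silhouette: bool = True,
) -> ClusterResult:
    """Best-of-restarts k-means on condition profiles.

    Clusters are re-indexed 1..k in a deterministic order (descending
    early-vs-invitro centroid shift, then late-vs-invitro) so repeated runs
    with one seed are bit-identical and reports are stable.  Centroids are
    recomputed as member means on the condition profiles.
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of peaks {len(profiles)}")
    if not np.isfinite(profiles.values).all():
        raise ValueError("profiles must be finite")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(profiles.values)
    raw_centroids = (
        profiles.groupby(pd.Series(raw_labels, index=profiles.index)).mean()
    )
    order = _order_clusters(raw_centroids)
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series(
        [relabel[c] for c in raw_labels], index=profiles.index, name="cluster"
    )
    centroids = raw_centroids.loc[order]
    centroids.index = pd.Index(range(1, k + 1), name="cluster")
    archetype = {
        c: annotate_archetype(centroids.loc[c], delta=delta) for c in centroids.index
    }
    sil = None
    if compute_silhouette and 1 < k < len(profiles):
        sil = float(silhouette_score(profiles.values, labels.values))
    return ClusterResult(
        labels=labels,
        centroids=centroids,
        k=k,
        archetype=archetype,
        seed=seed,
        inertia=float(km.inertia_),
        silhouette=sil,
    )
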