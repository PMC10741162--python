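"""Trajectory inference: z-scoring, consensus agglomerative clustering and
U/D/P temporal pattern labeling.

Time-significant features are z-scored per feature across the study
samples of one wound type, clustered by complete-linkage agglomerative
clustering on cosine distance, with the cluster count chosen by rank
consensus across three internal indices (silhouette, Calinski-Harabasz,
Davies-Bouldin).  Cluster centroids (mean z per day) are then labeled
U (monotone rise), D (monotone fall) or P (interior peak), and numbered
by response timing: U/D by the first day the centroid crosses zero, P by
whether the Day-7 value sits above, near, or below the average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from sklearn.metrics.pairwise import cosine_distances

from .datamodel import FeatureTable, ValidationError

#: default monotonicity tolerance for pattern letters, in z units
PATTERN_TOL = 0.2
#: default Day-7 band half-width separating P1 / P2 / P3, in z units
P_TIMING_TAU = 0.3


@dataclass
class TrajectoryResult:
    """Outcome of trajectory inference on one wound type."""

    feature_ids: list[str]
    labels: np.ndarray                 # cluster index per feature, in [0, k)
    k: int
    metric_table: pd.DataFrame         # per candidate k: silhouette, CH, DB, mean_rank
    centroids: pd.DataFrame            # cluster x day mean z
    pattern_labels: dict[int, str] = field(default_factory=dict)

    def assignments(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.labels,
                "pattern": [self.pattern_labels.get(c, "") for c in self.labels],
            },
            index=pd.Index(self.feature_ids, name="feature_id"),
        )


def zscore_features(table: FeatureTable, wound_type: str | None = None) -> pd.DataFrame:
    """Per-feature z-scores of log2 intensity over study samples.

    Uses the population standard deviation; constant rows map to all
    zeros; missing values stay missing.
    """
    mask = table.study_mask(wound_type)
    if not mask.any():
        raise ValidationError(f"no study samples for wound type {wound_type!r}")
    sub = table.subset_samples(mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(sub.intensities > 0, np.log2(sub.intensities), np.nan)
    n_ok = (~np.isnan(x)).sum(axis=1)
    if np.any(n_ok < 2):
        bad = [fid for fid, n in zip(sub.feature_ids, n_ok) if n < 2]
        raise ValidationError(f"features with < 2 non-missing values: {bad[:5]}")
    mean = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, keepdims=True)  # population sd
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mean) / sd, 0.0)
    z = np.where(np.isnan(x), np.nan, z)
    return pd.DataFrame(z, index=pd.Index(sub.feature_ids, name="feature_id"),
                        columns=sub.sample_ids)


def day_profile(z: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Reduce a feature x sample z-matrix to feature x day mean profiles."""
    days = sample_meta.loc[z.columns, "day"]
    if days.isna().any():
        raise ValidationError("day_profile requires study samples with a day")
    uniq = sorted(days.unique())
    cols = {}
    for d in uniq:
        block = z.loc[:, days[days == d].index]
        if block.shape[1] == 0:
            raise ValidationError(f"day {d} has no samples")
        cols[d] = block.mean(axis=1, skipna=True)
    return pd.DataFrame(cols)


def _distance_matrix(z: np.ndarray) -> np.ndarray:
    """Pairwise cosine distance with missing z treated as 0 and the
    zero-vector convention (distance 1 to everything)."""
    z0 = np.nan_to_num(z, nan=0.0)
    norms = np.linalg.norm(z0, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn("zero z-vectors assigned cosine distance 1 to all others")
    dist = cosine_distances(z0)
    if zero.any():
        dist[zero, :] = 1.0
        dist[:, zero] = 1.0
    np.fill_diagonal(dist, 0.0)
    return dist


def cluster_features(z, k: int) -> np.ndarray:
    """Complete-linkage agglomerative clustering on cosine distance,
    cut at exactly ``k`` clusters."""
    z = np.asarray(z, dtype=float)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if z.shape[0] < k:
        raise ValidationError(f"need at least k={k} features, have {z.shape[0]}")
    dist = _distance_matrix(z)
    model = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage="complete")
    return model.fit_predict(dist)


def consensus_from_metrics(metric_table: pd.DataFrame) -> int:
    """Pick k by mean rank over (silhouette: high good, CH: high good,
    DB: low good); ties go to the smaller k."""
    ranks = pd.DataFrame(index=metric_table.index)
    ranks["silhouette"] = rankdata(-metric_table["silhouette"])
    ranks["calinski_harabasz"] = rankdata(-metric_table["calinski_harabasz"])
    ranks["davies_bouldin"] = rankdata(metric_table["davies_bouldin"])
    mean_rank = ranks.mean(axis=1)
    best = mean_rank[mean_rank == mean_rank.min()]
    return int(best.index.min())


def select_k_consensus(z, k_range=range(2, 11)) -> tuple[int, pd.DataFrame]:
    """Cluster at each candidate k and choose the consensus cluster count.

    Silhouette is computed on the cosine distance matrix; Calinski-
    Harabasz and Davies-Bouldin on the (zero-filled) z-vectors in
    Euclidean geometry.
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    if n < 4:
        raise ValidationError("need at least 4 features to select k")
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValidationError("empty candidate k range")
    dist = _distance_matrix(z)
    z0 = np.nan_to_num(z, nan=0.0)
    rows = []
    for k in ks:
        labels = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage="complete"
        ).fit_predict(dist)
        rows.append({
            "k": k,
            "silhouette": silhouette_score(dist, labels, metric="precomputed"),
            "calinski_harabasz": calinski_harabasz_score(z0, labels),
            "davies_bouldin": davies_bouldin_score(z0, labels),
        })
    table = pd.DataFrame(rows).set_index("k")
    k_best = consensus_from_metrics(table)
    ranks = pd.DataFrame({
        "silhouette": rankdata(-table["silhouette"]),
        "calinski_harabasz": rankdata(-table["calinski_harabasz"]),
        "davies_bouldin": rankdata(table["davies_bouldin"]),
    }, index=table.index)
    table["mean_rank"] = ranks.mean(axis=1)
    return k_best, table


def classify_pattern(centroid, tol: float = PATTERN_TOL) -> str:
    """Classify a per-day centroid as U (monotone rise), D (monotone
    fall) or P (interior extremum), with ``tol`` slack on step
    monotonicity."""
    c = np.asarray(centroid, dtype=float)
    if c.size < 3:
        raise ValidationError("centroid must cover at least 3 days")
    steps = np.diff(c)
    total = c[-1] - c[0]
    if np.all(steps >= -tol) and total > 0:
        return "U"
    if np.all(steps <= tol) and total < 0:
        return "D"
    return "P"


def peak_day_index(centroid) -> int:
    """Interior-extremum position for P patterns: argmax, or argmax of
    |deviation| for valley-shaped centroids."""
    c = np.asarray(centroid, dtype=float)
    imax = int(np.argmax(c))
    if imax in (0, c.size - 1):  # valley-shaped
        warnings.warn("valley-shaped centroid; using argmax |deviation| as peak")
        return int(np.argmax(np.abs(c)))
    return imax


def assign_timing_labels(clusters: list[tuple[np.ndarray, str]],
                         tau: float = P_TIMING_TAU) -> list[str]:
    """Attach timing numerals to lettered clusters.

    ``clusters`` is a list of ``(centroid over days, letter)``.  U and D
    clusters are numbered by the first day index at which the centroid
    crosses zero (rising through zero for U, falling for D); P clusters
    by Day-7 (first-grid-day) value: above ``+tau`` -> earliest, within
    the band -> middle, below ``-tau`` -> latest.  Numerals within a
    letter are consecutive from 1; more than 3 clusters of one letter
    continue 4, 5, ... with a warning.
    """
    keys: list[tuple[str, float, float]] = []
    for idx, (centroid, letter) in enumerate(clusters):
        c = np.asarray(centroid, dtype=float)
        if letter == "U":
            crossing = np.nonzero(c >= 0)[0]
            key = float(crossing[0]) if crossing.size else float(c.size)
            keys.append((letter, key, -c[0]))
        elif letter == "D":
            crossing = np.nonzero(c <= 0)[0]
            key = float(crossing[0]) if crossing.size else float(c.size)
            keys.append((letter, key, c[0]))
        elif letter == "P":
            first = c[0]
            category = 1.0 if first > tau else (2.0 if first >= -tau else 3.0)
            keys.append((letter, category, -first))
        else:
            raise ValidationError(f"unknown pattern letter {letter!r}")

    labels = [""] * len(clusters)
    for letter in sorted({k[0] for k in keys}):
        members = [i for i, k in enumerate(keys) if k[0] == letter]
        members.sort(key=lambda i: (keys[i][1], keys[i][2]))
        if len(members) > 3:
            warnings.warn(f"more than 3 clusters share letter {letter}")
        for numeral, i in enumerate(members, start=1):
            labels[i] = f"{letter}{numeral}"
    return labels


def infer_trajectories(table: FeatureTable, wound_type: str,
                       feature_ids: list[str] | None = None,
                       k_range=range(2, 11),
                       tol: float = PATTERN_TOL,
                       tau: float = P_TIMING_TAU) -> TrajectoryResult:
    """Full trajectory stage: z-score, consensus clustering, pattern labels."""
    sub = table.subset_features(feature_ids) if feature_ids is not None else table
    z = zscore_features(sub, wound_type)
    meta = sub.sample_frame()
    k, metric_table = select_k_consensus(z.to_numpy(), k_range)
    labels = cluster_features(z.to_numpy(), k)
    profiles = day_profile(z, meta)
    centroids = profiles.groupby(labels).mean()
    letters = {c: classify_pattern(centroids.loc[c].to_numpy(), tol=tol)
               for c in centroids.index}
    named = assign_timing_labels(
        [(centroids.loc[c].to_numpy(), letters[c]) for c in centroids.index], tau=tau
    )
    pattern_labels = {int(c): name for c, name in zip(centroids.index, named)}
    return TrajectoryResult(
        feature_ids=list(z.index),
        labels=labels,
        k=k,
        metric_table=metric_table,
        centroids=centroids,
        pattern_labels=pattern_labels,
    )
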