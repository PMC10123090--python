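"""Per-track TAMSD clustering.

Tracks are summarized by their time-averaged MSD at the first four frame
lags; k-means on the standardized log10-TAMSD feature vectors groups
tracks with similar dynamic behavior. The number of groups is supplied by
the caller — by convention the number of diffusive states accepted by SQD
model selection — and never refitted here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .msd import compute_tamsd
from .tracks import TrackSet

__all__ = ["ClusterResult", "cluster_tamsd"]


@dataclass(frozen=True)
class ClusterResult:
    """TAMSD clustering output, clusters ordered by descending mean TAMSD.

    ``labels`` maps each clustered track (by position in ``track_ids``) to
    a cluster in [0, k); cluster 0 is the most mobile group. Tracks too
    short to populate all requested lags are excluded and listed in
    ``excluded_track_ids``.
    """

    k: int
    track_ids: np.ndarray
    labels: np.ndarray
    mean_curves: np.ndarray  # (k, n_lags) mean TAMSD per cluster, µm²
    lags: np.ndarray  # seconds
    occupancies: np.ndarray  # fraction of clustered tracks per cluster
    excluded_track_ids: np.ndarray

    def summary(self) -> str:
        lines = [f"TAMSD clustering: k = {self.k}, "
                 f"{len(self.track_ids)} tracks ({len(self.excluded_track_ids)} excluded)"]
        for c in range(self.k):
            tam = ", ".join(f"{v:.3g}" for v in self.mean_curves[c])
            lines.append(
                f"  cluster {c}: occupancy {100 * self.occupancies[c]:.1f}%  "
                f"mean TAMSD [{tam}] µm²"
            )
        return "\n".join(lines)


def cluster_tamsd(ts: TrackSet, k: int, max_lag: int = 4, seed: int = 0,
                  n_init: int = 10) -> ClusterResult:
    """K-means clustering of per-track log10 TAMSD feature vectors.

    Features are the TAMSD values at lags 1..max_lag frames (last-point
    exclusion applied), log10-transformed and standardized. Tracks whose
    TAMSD is zero at any lag (perfectly stationary) are floored to the
    smallest positive TAMSD observed before the log transform.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    feats, ids, excluded = [], [], []
    for t in ts.tracks:
        try:
            curve = compute_tamsd(t, ts.frame_interval, max_lag=max_lag)
        except ValueError:
            excluded.append(t.track_id)
            continue
        feats.append(curve.msd)
        ids.append(t.track_id)
    if excluded:
        warnings.warn(f"{len(excluded)} tracks too short for TAMSD; excluded")
    if len(ids) < k:
        raise ValueError(f"k = {k} exceeds the {len(ids)} clusterable tracks")
    lags = np.arange(1, max_lag + 1) * ts.frame_interval
    feats = np.asarray(feats)

    positive = feats[feats > 0]
    floor = positive.min() if len(positive) else 1.0
    logf = np.log10(np.maximum(feats, floor))
    sd = logf.std(axis=0)
    sd[sd == 0] = 1.0
    z = (logf - logf.mean(axis=0)) / sd

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(z)

    # reorder clusters by descending mean TAMSD (cluster 0 = most mobile)
    means = np.array([
        feats[raw_labels == c].mean(axis=1).mean() if np.any(raw_labels == c) else -np.inf
        for c in range(k)
    ])
    order = np.argsort(means)[::-1]
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[raw_labels]

    mean_curves = np.zeros((k, max_lag))
    occ = np.zeros(k)
    for c in range(k):
        sel = labels == c
        occ[c] = sel.mean()
        if sel.any():
            mean_curves[c] = feats[sel].mean(axis=0)
        else:
            warnings.warn(f"cluster {c} is empty")
    return ClusterResult(
        k=k, track_ids=np.asarray(ids), labels=labels, mean_curves=mean_curves,
        lags=lags, occupancies=occ, excluded_track_ids=np.asarray(excluded),
    )
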