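"""Signal matrices around peak centres and k-means classification of
regions into gain / loss / common classes.

Each union region contributes one row per condition: the 10-kb window
around the region centre split into 50 matrix bins (defaults), each the
mean of the underlying track bins it overlaps.  Rows from all conditions
are concatenated into one feature vector per region and clustered with
seeded k-means (k-means++ initialization, Lloyd iterations, best of
``n_init`` restarts).  Clusters are then labelled gain / loss / common by
a pseudocounted fold change between the two conditions' cluster means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .core_io import BinnedTrack, Region

__all__ = [
    "MatrixConfig",
    "ClusterConfig",
    "SignalMatrix",
    "extract_signal_matrix",
    "kmeans_cluster",
    "classify_clusters",
]


@dataclass(frozen=True)
class MatrixConfig:
    """window bp around the region centre, split into n_bins matrix bins."""

    window: int = 10_000
    n_bins: int = 50

    def __post_init__(self):
        if self.window % self.n_bins != 0:
            raise ValueError("window must be divisible by n_bins")

    @property
    def step(self) -> int:
        return self.window // self.n_bins


@dataclass(frozen=True)
class ClusterConfig:
    k: int = 4
    seed: int = 0
    n_init: int = 10
    max_iter: int = 300
    fold_threshold: float = 1.5  # pseudocounted fold for gain/loss labels
    # Cluster on unit-normalized rows by default: Euclidean distance on raw
    # rows sorts regions by domain extent before condition pattern, so two
    # short domains with opposite gain/loss patterns sit closer than two
    # common domains of different widths.  Normalizing each feature row
    # makes the condition pattern the dominant axis; set False for raw.
    row_normalize: bool = True

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")


@dataclass
class SignalMatrix:
    """regions x n_bins mean signal, one matrix per condition."""

    region_ids: list[str]
    conditions: list[str]
    matrices: dict[str, np.ndarray]  # condition -> (n_regions, n_bins)

    def __post_init__(self):
        n = len(self.region_ids)
        for cond in self.conditions:
            m = self.matrices[cond]
            if m.shape[0] != n:
                raise ValueError(f"condition {cond}: row count mismatch")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"condition {cond}: non-finite matrix values")

    def features(self) -> np.ndarray:
        """Per-region feature vectors: per-condition rows concatenated."""
        return np.hstack([self.matrices[c] for c in self.conditions])

    def to_frame(self):
        import pandas as pd
        cols = {}
        for cond in self.conditions:
            m = self.matrices[cond]
            for j in range(m.shape[1]):
                cols[f"{cond}_bin{j:02d}"] = m[:, j]
        return pd.DataFrame(cols, index=pd.Index(self.region_ids, name="region_id"))


def extract_signal_matrix(tracks_by_condition: dict[str, BinnedTrack],
                          regions: list[Region],
                          config: MatrixConfig = MatrixConfig()) -> SignalMatrix:
    """Build per-condition signal matrices in a window around region centres.

    For each region the centre is ``floor((start+end)/2)``; the window
    ``[c - window/2, c + window/2)`` is split into ``n_bins`` equal matrix
    bins, each valued as the mean of the track bins it overlaps, with
    positions beyond chromosome ends contributing zeros.
    """
    conditions = list(tracks_by_condition)
    if not conditions:
        raise ValueError("need at least one condition")
    ref = tracks_by_condition[conditions[0]]
    w = ref.bin_width
    if config.step % w != 0:
        raise ValueError(f"window/n_bins = {config.step} must be divisible by track bin width {w}")
    per_step = config.step // w
    half = config.window // 2

    region_ids = [r.name if r.name is not None else str(i + 1) for i, r in enumerate(regions)]
    matrices = {c: np.zeros((len(regions), config.n_bins)) for c in conditions}
    for cond, track in tracks_by_condition.items():
        if not track.same_shape(ref):
            raise ValueError("all condition tracks must share genome and bin_width")
        M = matrices[cond]
        for i, r in enumerate(regions):
            v = track.values[r.chrom]
            n = len(v)
            centre = (r.start + r.end) // 2
            w0 = centre - half
            # track-bin index of the first bin of each matrix bin; matrix
            # bins straddling the grid take the mean over overlapped bins
            for j in range(config.n_bins):
                mb_start = w0 + j * config.step
                mb_end = mb_start + config.step
                b0 = int(np.floor(mb_start / w))
                b1 = int(np.ceil(mb_end / w))
                vals = [v[b] if 0 <= b < n else 0.0 for b in range(b0, b1)]
                M[i, j] = float(np.mean(vals))
    return SignalMatrix(region_ids, conditions, matrices)


def kmeans_cluster(matrix: SignalMatrix, config: ClusterConfig) -> np.ndarray:
    """Cluster regions on concatenated per-condition features.

    Returns an integer label per region; deterministic given the seed.
    """
    X = matrix.features()
    if X.shape[0] < config.k:
        raise ValueError(f"fewer regions ({X.shape[0]}) than clusters ({config.k})")
    if config.row_normalize:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        X = np.where(norms > 0, X / np.where(norms == 0, 1, norms), X)
    km = KMeans(n_clusters=config.k, init="k-means++", n_init=config.n_init,
                max_iter=config.max_iter, random_state=config.seed)
    return km.fit_predict(X)


def classify_clusters(cluster_means: dict[int, tuple[float, float]],
                      fold_threshold: float = 1.5,
                      pseudocount: float = 1.0) -> dict[int, str]:
    """Label clusters gain / loss / common from per-condition mean signal.

    ``cluster_means`` maps cluster id -> (mean in condition A, mean in
    condition B).  With pseudocount eps, a cluster is *gain* when
    (mB+eps)/(mA+eps) >= fold_threshold, *loss* on the mirrored ratio, else
    *common*.
    """
    labels: dict[int, str] = {}
    for cid, (ma, mb) in cluster_means.items():
        ra = (mb + pseudocount) / (ma + pseudocount)
        rb = (ma + pseudocount) / (mb + pseudocount)
        if ra >= fold_threshold:
            labels[cid] = "gain"
        elif rb >= fold_threshold:
            labels[cid] = "loss"
        else:
            labels[cid] = "common"
    return labels


def cluster_condition_means(matrix: SignalMatrix, assignment: np.ndarray,
                            condition_pair: tuple[str, str]) -> dict[int, tuple[float, float]]:
    """Mean signal per cluster for the two conditions being compared."""
    a, b = condition_pair
    out: dict[int, tuple[float, float]] = {}
    for cid in np.unique(assignment):
        rows = assignment == cid
        out[int(cid)] = (float(matrix.matrices[a][rows].mean()),
                         float(matrix.matrices[b][rows].mean()))
    return out
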