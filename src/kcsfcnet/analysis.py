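"""Group-level analysis and connectivity interpretation.

Two strands:

* **Subject grouping** — k-means (k=3) on the six-column score matrix, with
  clusters relabelled G I/G II/G III by decreasing mean accuracy, a PCA
  first-component ordering of subjects, label transfer to new score
  matrices by nearest fitted centroid, and a t-SNE layout for visualising
  how per-subject connectivity patterns organise by performance.

* **Connection pruning and relevance** — a two-sample Kolmogorov–Smirnov
  test per channel pair contrasts the trial-wise connectivity values of the
  two classes; pairs with p ≤ 0.05 are retained (no multiple-testing
  correction — raw p-values are thresholded deliberately, so the retained
  set has the test's per-connection, not family-wise, error level).
  A quadratic Rényi entropy over the significance weights summarises how
  many well-spread discriminative connections survive; percentile edge
  lists and per-channel relevance scores support topographic export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .model import ConnectivityTensor, pair_indices

__all__ = [
    "PValueMatrix",
    "GroupAssignment",
    "ks_two_sample",
    "prune_connections",
    "renyi_entropy",
    "SubjectClusterer",
    "cluster_subjects",
    "order_subjects",
    "transfer_labels",
    "top_percentile_edges",
    "channel_relevance",
    "tsne_layout",
    "montage_positions",
]

GROUP_NAMES = ("G I", "G II", "G III")
_EXACT_KS_MAX = 25  # exact two-sided p-value below this pooled sample size


@dataclass
class PValueMatrix:
    """Symmetric per-pair two-sample KS p-values with a significance mask.

    The diagonal (self-connection) is untested and set to p=1 / mask False.
    """

    p: np.ndarray
    alpha: float = 0.05
    mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        nc = self.p.shape[0]
        if self.p.shape != (nc, nc):
            raise ValueError("p must be square")
        if not np.allclose(self.p, self.p.T):
            raise ValueError("p must be symmetric")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        self.p[np.diag_indices(nc)] = 1.0
        self.mask = self.p <= self.alpha
        self.mask[np.diag_indices(nc)] = False

    @property
    def n_channels(self) -> int:
        return self.p.shape[0]

    def significant_pairs(self) -> list[tuple[int, int]]:
        i, j = pair_indices(self.n_channels)
        sel = self.mask[i, j]
        return list(zip(i[sel].tolist(), j[sel].tolist()))


@dataclass
class GroupAssignment:
    """k-means subject grouping with performance-ordered labels.

    ``labels`` maps each subject to "G I"/"G II"/"G III"; centroids are
    stored in that order, so centroid mean accuracy decreases G I → G III.
    """

    labels: dict[str, str]
    centroids: np.ndarray
    ordering: list[str]


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    D = sup |ECDF_a − ECDF_b|; the p-value is exact (equivalent to the
    full permutation distribution for tie-free data) when the pooled
    sample size is at most 25, asymptotic otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # both samples constant and equal: identical distributions
        return 0.0, 1.0
    method = "exact" if a.size + b.size <= _EXACT_KS_MAX else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def prune_connections(conn: ConnectivityTensor, labels: np.ndarray,
                      alpha: float = 0.05) -> PValueMatrix:
    """Per-pair KS contrast of class-0 vs class-1 connectivity values.

    No multiple-testing correction is applied: the mask keeps every pair
    with raw p ≤ alpha.
    """
    labels = np.asarray(labels)
    vals = conn.values
    if vals.shape[0] != labels.shape[0]:
        raise ValueError("labels length must match the number of trials")
    for cls in (0, 1):
        if np.sum(labels == cls) < 2:
            raise ValueError(f"class {cls} needs at least 2 trials")
    nc = conn.n_channels
    p = np.ones((nc, nc))
    sel0, sel1 = labels == 0, labels == 1
    for (ci, cj), col in zip(conn.pair_index, vals.T):
        _, pv = ks_two_sample(col[sel0], col[sel1])
        p[ci, cj] = p[cj, ci] = pv
    return PValueMatrix(p=p, alpha=alpha)


def renyi_entropy(pmat: PValueMatrix, variant: str = "weights") -> float:
    """Quadratic Rényi entropy (bits) of the pruned connectivity pattern.

    ``variant="weights"`` (default): each significant pair i carries weight
    w_i = 1 − p_i; with q = w / Σw the entropy is H₂ = −log₂ Σ q_i².
    It is 0 when at most one pair survives and log₂ m when m pairs survive
    with equal weight, so it measures both how many and how evenly spread
    the retained discriminative connections are.

    ``variant="spectral"``: the same functional applied to the normalised
    singular-value spectrum of the masked weight matrix, a matrix-based
    alternative that is sensitive to how connections organise into
    channel communities rather than only to their count.
    """
    i, j = pair_indices(pmat.n_channels)
    w = np.where(pmat.mask[i, j], 1.0 - pmat.p[i, j], 0.0)
    if variant == "weights":
        tot = w.sum()
        if tot <= 0:
            return 0.0
        q = w / tot
        return float(-np.log2(np.sum(q**2)))
    if variant == "spectral":
        nc = pmat.n_channels
        W = np.zeros((nc, nc))
        W[i, j] = W[j, i] = w
        s = np.linalg.svd(W, compute_uv=False)
        tot = s.sum()
        if tot <= 0:
            return 0.0
        q = s / tot
        return float(-np.log2(np.sum(q**2)))
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

class SubjectClusterer(BaseEstimator):
    """k-means subject grouping on the score matrix, sklearn-style.

    Clusters are relabelled so group I has the highest centroid mean
    accuracy (first score column).  ``predict`` assigns new subjects to the
    *fitted* centroids by Euclidean distance (ties to the lowest-index,
    i.e. best, group) without refitting.
    """

    def __init__(self, n_clusters: int = 3, n_init: int = 10,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, scores: pd.DataFrame):
        X = np.asarray(scores, dtype=float)
        if X.shape[0] < self.n_clusters:
            raise ValueError(
                f"{X.shape[0]} subjects cannot form {self.n_clusters} clusters"
            )
        if np.ptp(X, axis=0).max() == 0:
            warnings.warn("all subjects identical: degenerate clustering, all G I")
            self.centroids_ = np.tile(X[0], (self.n_clusters, 1))
            raw = np.zeros(X.shape[0], dtype=int)
        else:
            km = KMeans(n_clusters=self.n_clusters, n_init=self.n_init,
                        random_state=self.random_state)
            raw = km.fit_predict(X)
            self.centroids_ = km.cluster_centers_
        # relabel by decreasing centroid mean accuracy (column 0)
        order = np.argsort(-self.centroids_[:, 0], kind="stable")
        self.centroids_ = self.centroids_[order]
        remap = np.empty(self.n_clusters, dtype=int)
        remap[order] = np.arange(self.n_clusters)
        self.labels_ = remap[raw]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, scores: pd.DataFrame) -> np.ndarray:
        X = np.asarray(scores, dtype=float)
        if X.shape[1] != self.centroids_.shape[1]:
            raise ValueError(
                f"score matrix has {X.shape[1]} columns, centroids have "
                f"{self.centroids_.shape[1]}"
            )
        d = np.linalg.norm(X[:, None, :] - self.centroids_[None, :, :], axis=2)
        return np.argmin(d, axis=1)  # argmin takes the lowest index on ties


def cluster_subjects(scores: pd.DataFrame, k: int = 3,
                     seed: int | None = 0) -> GroupAssignment:
    """Group subjects into G I/G II/G III from the score matrix."""
    clu = SubjectClusterer(n_clusters=k, random_state=seed).fit(scores)
    names = [GROUP_NAMES[g] if g < len(GROUP_NAMES) else f"G {g + 1}"
             for g in clu.labels_]
    ordering = order_subjects(scores)
    return GroupAssignment(
        labels=dict(zip(scores.index.tolist(), names)),
        centroids=clu.centroids_,
        ordering=ordering,
    )


def order_subjects(scores: pd.DataFrame) -> list[str]:
    """Subjects in descending order of their first-principal-component score.

    The component sign is chosen to correlate positively with the accuracy
    column, so the ordering runs best-to-worst.
    """
    X = np.asarray(scores, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects to order")
    if np.ptp(X, axis=0).max() == 0:
        warnings.warn("zero-variance score matrix: keeping input order")
        return scores.index.tolist()
    proj = PCA(n_components=1).fit_transform(X - X.mean(axis=0)).ravel()
    acc = X[:, 0]
    if np.std(acc) > 0 and np.corrcoef(proj, acc)[0, 1] < 0:
        proj = -proj
    order = np.argsort(-proj, kind="stable")
    return [scores.index[i] for i in order]


def transfer_labels(fitted: GroupAssignment, new_scores: pd.DataFrame) -> dict[str, str]:
    """Assign new subjects to the previously fitted centroids (no refit)."""
    X = np.asarray(new_scores, dtype=float)
    if X.shape[1] != fitted.centroids.shape[1]:
        raise ValueError(
            f"score matrix has {X.shape[1]} columns, expected "
            f"{fitted.centroids.shape[1]}"
        )
    d = np.linalg.norm(X[:, None, :] - fitted.centroids[None, :, :], axis=2)
    idx = np.argmin(d, axis=1)
    return {s: GROUP_NAMES[g] for s, g in zip(new_scores.index.tolist(), idx)}


# ---------------------------------------------------------------------------
# edges, relevance, layout
# ---------------------------------------------------------------------------

def top_percentile_edges(mean_conn: dict[str, np.ndarray],
                         pair_index: list[tuple[int, int]],
                         q: float = 99.0) -> dict[str, pd.DataFrame]:
    """Strongest connections per subject after joint min-max normalisation.

    Connectivity vectors of all provided subjects are normalised together
    (one min, one max across the pool), then every pair whose normalised
    strength reaches the q-th percentile of the pooled values is returned
    per subject as an edge table (channel_a, channel_b, strength).
    """
    if not mean_conn:
        raise ValueError("need at least one subject")
    if not 0.0 <= q < 100.0:
        raise ValueError(f"percentile must lie in [0, 100), got {q}")
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in mean_conn.values()])
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        warnings.warn("constant connectivity across the pool: no edges selected")
        return {s: pd.DataFrame(columns=["channel_a", "channel_b", "strength"])
                for s in mean_conn}
    thresh = np.percentile((pooled - lo) / (hi - lo), q)
    out = {}
    for subject, v in mean_conn.items():
        norm = (np.asarray(v, dtype=float) - lo) / (hi - lo)
        sel = norm >= thresh
        out[subject] = pd.DataFrame({
            "channel_a": [pair_index[k][0] for k in np.flatnonzero(sel)],
            "channel_b": [pair_index[k][1] for k in np.flatnonzero(sel)],
            "strength": norm[sel],
        })
    return out


def channel_relevance(source: str, obj, n_channels: int | None = None) -> np.ndarray:
    """Per-channel relevance scores in [0, 1] for topographic maps.

    ``source="pvalues"``: rel(c) = Σ_{c′≠c} (1 − p_{cc′}) over significant
    pairs of a :class:`PValueMatrix`.  ``source="weights"``: rel(c) sums,
    over pairs containing c, the class-averaged |v| of the readout weight
    matrix (M × 2).  Both are normalised by their maximum; an all-zero
    pattern stays all-zero.
    """
    if source == "pvalues":
        pmat: PValueMatrix = obj
        contrib = np.where(pmat.mask, 1.0 - pmat.p, 0.0)
        rel = contrib.sum(axis=1)
    elif source == "weights":
        v = np.asarray(obj, dtype=float)
        if v.ndim != 2:
            raise ValueError("readout weights must be (pairs, classes)")
        m = v.shape[0]
        nc = n_channels or int(round((1 + np.sqrt(1 + 8 * m)) / 2))
        i, j = pair_indices(nc)
        if i.size != m:
            raise ValueError(f"{m} pairs inconsistent with {nc} channels")
        w = np.abs(v).mean(axis=1)
        rel = np.zeros(nc)
        np.add.at(rel, i, w)
        np.add.at(rel, j, w)
    else:
        raise ValueError(f"unknown source {source!r}")
    top = rel.max()
    return rel / top if top > 0 else rel


def tsne_layout(scores: pd.DataFrame, perplexity: float = 10.0,
                seed: int | None = 0) -> np.ndarray:
    """2-D t-SNE embedding of the score-matrix rows, deterministic per seed."""
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be below n_subjects ({n})")
    if n <= 3 * perplexity:
        warnings.warn(
            f"n_subjects ({n}) <= 3x perplexity ({perplexity}): embedding may be unstable"
        )
    emb = TSNE(n_components=2, perplexity=perplexity, init="pca",
               random_state=seed).fit_transform(X)
    return np.asarray(emb, dtype=float)


def montage_positions(channel_names: list[str]) -> np.ndarray:
    """2-D scalp coordinates for standard 10-10/10-05 channel names.

    Positions come from mne's ``standard_1005`` montage (x, y of the
    head-frame coordinates); unknown names raise.
    """
    import mne

    montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    lookup = {name.lower(): xyz for name, xyz in pos.items()}
    out = []
    for name in channel_names:
        if name.lower() not in lookup:
            raise KeyError(f"channel {name!r} not in the standard 10-05 montage")
        out.append(lookup[name.lower()][:2])
    return np.asarray(out, dtype=float)
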