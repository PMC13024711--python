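"""DTW distance matrices, PAM K-medoids and cluster interpretation.

Sequences encoded as numeric series (raw ordinal action codes, per-move Δd,
or the post-move d series) are compared with classic unnormalized dynamic
time warping:

    D(i, j) = |x_i - y_j| + min(D(i-1, j), D(i, j-1), D(i-1, j-1))

(the ``symmetric1`` step pattern; ``symmetric2`` doubles the diagonal
cost).  The pairwise matrix feeds deterministic PAM (partitioning around
medoids, BUILD initialization + single-swap local search), scored by the
mean silhouette and a medoid-based Calinski-Harabasz ratio.  Two-cluster
solutions are interpreted by pooled-variance t-tests over per-sequence
features with BH correction and Cohen's d.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from numba import njit
from sklearn.metrics import silhouette_samples

from .effectiveness import EncodedSequence
from .ngram import bh_adjust

__all__ = [
    "dtw_distance",
    "dtw_matrix",
    "ClusteringResult",
    "pam_cluster",
    "silhouette_mean",
    "ch_index",
    "scan_k",
    "compare_cluster_features",
    "unigram_frequency_features",
]


@njit(cache=True)
def _dtw_core(x, y, diag_weight):  # pragma: no cover - exercised via dtw_distance
    n, m = x.shape[0], y.shape[0]
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    for j in range(m + 1):
        prev[j] = np.inf
    prev[0] = 0.0
    for i in range(1, n + 1):
        for j in range(m + 1):
            cur[j] = np.inf
        for j in range(1, m + 1):
            c = abs(x[i - 1] - y[j - 1])
            best = prev[j] + c
            alt = cur[j - 1] + c
            if alt < best:
                best = alt
            alt = prev[j - 1] + diag_weight * c
            if alt < best:
                best = alt
            cur[j] = best
        prev, cur = cur, prev
    return prev[m]


def dtw_distance(x, y, step_pattern: str = "symmetric1") -> float:
    """Unnormalized DTW distance between two numeric series.

    ``symmetric1`` (default) weights every step equally; ``symmetric2``
    doubles the local cost on diagonal steps.  No warping window or
    endpoint relaxation.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("DTW is undefined for empty series")
    if step_pattern not in ("symmetric1", "symmetric2"):
        raise ValueError(f"unknown step pattern {step_pattern!r}")
    return float(_dtw_core(x, y, 2.0 if step_pattern == "symmetric2" else 1.0))


def dtw_matrix(seqs: Sequence, step_pattern: str = "symmetric1") -> np.ndarray:
    """Symmetric pairwise DTW matrix over a list of (possibly ragged) series."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    arrs = [np.asarray(s, dtype=np.float64).ravel() for s in seqs]
    n = len(arrs)
    D = np.zeros((n, n))
    w = 2.0 if step_pattern == "symmetric2" else 1.0
    for i in range(n):
        if arrs[i].size == 0:
            raise ValueError(f"sequence {i} is empty")
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _dtw_core(arrs[i], arrs[j], w)
    return D


@dataclass
class ClusteringResult:
    k: int
    medoids: list[int]
    assignment: np.ndarray
    objective: float
    silhouette: float
    ch: float


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        # gain of adding h: total reduction in distance-to-nearest-medoid
        gains = np.maximum(cur[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return sorted(medoids)


def pam_cluster(D: np.ndarray, k: int) -> ClusteringResult:
    """Deterministic PAM: BUILD, then best improving single swap until none.

    Ties are broken toward the lowest index, so repeated runs are
    identical; points are assigned to their nearest medoid (lowest medoid
    index on ties).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if not 2 <= k < n:
        raise ValueError(f"k={k} out of range [2, {n - 1}]")
    medoids = _pam_build(D, k)
    objective = D[:, medoids].min(axis=1).sum()
    improved = True
    while improved:
        improved = False
        best = (objective, None)
        non_medoids = [h for h in range(n) if h not in medoids]
        for mi, m in enumerate(medoids):
            for h in non_medoids:
                cand = medoids.copy()
                cand[mi] = h
                obj = D[:, cand].min(axis=1).sum()
                if obj < best[0] - 1e-12:
                    best = (obj, (mi, h))
        if best[1] is not None:
            mi, h = best[1]
            medoids[mi] = h
            medoids.sort()
            objective = best[0]
            improved = True
    medoid_arr = np.array(medoids)
    assignment = np.argmin(D[:, medoid_arr], axis=1)
    sil = silhouette_mean(D, assignment)[0]
    ch = ch_index(D, assignment, medoids)
    return ClusteringResult(k, medoids, assignment, float(objective), sil, ch)


def silhouette_mean(D: np.ndarray, assignment) -> tuple[float, np.ndarray]:
    """Mean and per-point silhouette over a precomputed distance matrix."""
    labels = np.asarray(assignment)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    s = silhouette_samples(np.asarray(D, dtype=float), labels, metric="precomputed")
    return float(s.mean()), s


def ch_index(D: np.ndarray, assignment, medoids: Sequence[int]) -> float:
    """Medoid-based Calinski-Harabasz ratio for a precomputed distance matrix.

    With m* the global medoid, W = sum_c sum_{i in c} D[i, m_c]^2 and
    B = sum_c n_c * D[m_c, m*]^2; CH = (B / (k-1)) / (W / (n-k)).
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(assignment)
    medoids = list(medoids)
    n, k = D.shape[0], len(medoids)
    if k < 2:
        raise ValueError("CH requires at least 2 clusters")
    m_star = int(np.argmin(D.sum(axis=1)))
    W = sum(float((D[labels == c, medoids[c]] ** 2).sum()) for c in range(k))
    B = sum(int((labels == c).sum()) * float(D[medoids[c], m_star] ** 2) for c in range(k))
    if W == 0.0:
        warnings.warn("zero within-cluster dispersion; CH reported as +inf")
        return math.inf
    return (B / (k - 1)) / (W / (n - k))


def scan_k(D: np.ndarray, k_range: Sequence[int] = range(2, 7)) -> pd.DataFrame:
    """PAM across a range of k, with both quality indices and best-k flags."""
    rows = []
    for k in k_range:
        res = pam_cluster(D, k)
        rows.append(
            {"k": k, "objective": res.objective, "silhouette": res.silhouette, "ch": res.ch}
        )
    df = pd.DataFrame(rows)
    df["best_silhouette"] = df["silhouette"] == df["silhouette"].max()
    df["best_ch"] = df["ch"] == df["ch"].max()
    return df


def compare_cluster_features(features: pd.DataFrame, assignment, alpha: float = 0.05) -> pd.DataFrame:
    """Two-cluster feature comparison: pooled t-tests, BH correction, Cohen's d.

    ``features`` has one row per sequence; requires exactly two clusters.
    Features with zero pooled variance are skipped with a warning.
    """
    labels = np.asarray(assignment)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("feature comparison requires exactly 2 clusters")
    a = features[labels == groups[0]]
    b = features[labels == groups[1]]
    n1, n2 = len(a), len(b)
    rows = []
    for col in features.columns:
        x, y = a[col].to_numpy(float), b[col].to_numpy(float)
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        if sp2 == 0:
            warnings.warn(f"feature {col!r} skipped: zero pooled variance")
            continue
        t, p = scipy.stats.ttest_ind(x, y, equal_var=True)
        rows.append(
            {
                "feature": col,
                "mean_1": x.mean(),
                "mean_2": y.mean(),
                "t": float(t),
                "df": n1 + n2 - 2,
                "p": float(p),
                "cohens_d": float((x.mean() - y.mean()) / math.sqrt(sp2)),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        p_adj, reject = bh_adjust(df["p"].to_numpy(), alpha=alpha)
        df["p_adj"] = p_adj
        df["significant"] = reject
    return df


def unigram_frequency_features(corpus: Sequence[EncodedSequence], merge_roles: bool = True) -> pd.DataFrame:
    """Per-sequence unigram frequency table from tagged token sequences.

    With ``merge_roles`` the role prefix (``"A: "``/``"B: "`` or the
    leading actor word of a raw tagged token) is stripped first, so
    identical actions by the two students share a column.
    """
    rows = []
    for seq in corpus:
        tokens = seq.tokens
        if merge_roles:
            tokens = [
                t[3:] if isinstance(t, str) and t[:3] in ("A: ", "B: ")
                else t[2:] if isinstance(t, str) and t[:2] in ("A ", "B ")
                else t
                for t in tokens
            ]
        rows.append(Counter(tokens))
    df = pd.DataFrame(rows).fillna(0.0)
    df.index = [seq.group_id for seq in corpus]
    return df[sorted(df.columns, key=str)]
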