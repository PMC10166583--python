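"""Cluster-marker ranking (MarkerFinder) and nearest-centroid label transfer.

MarkerFinder scores each feature against each cluster's *idealized profile*
— the 0/1 indicator vector of cluster membership — by Pearson correlation.
A feature is assigned to the cluster it correlates with most strongly, and
features are ranked within each cluster by descending r; the top hits are
the candidate distinguishing surface markers for that population. This is
the single-pass indicator-correlation form of the algorithm (no iterative
exclusion passes).

Label transfer is a deliberate nearest-centroid simplification of the
cellHarmony reference-alignment approach: each query event is assigned the
reference population whose centroid it correlates with best over the shared
(name-mapped) features, with a correlation floor below which events stay
"unassigned".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerAssignment",
    "ReferenceProfile",
    "marker_finder",
    "label_transfer",
    "read_reference_profiles",
]


@dataclass(frozen=True)
class MarkerAssignment:
    feature: str
    cluster: str
    r: float
    rank: int  # 1-based within cluster


@dataclass(frozen=True)
class ReferenceProfile:
    """Mean expression centroid of one reference population."""

    label: str
    centroid: Mapping[str, float]
    n_cells: int = 0


def marker_finder(
    X: np.ndarray,
    labels: Sequence[str],
    feature_names: Sequence[str],
    top_n: int = 3,
) -> list[MarkerAssignment]:
    """Assign each feature to its best-correlated cluster and rank within.

    For feature f and cluster c, r(f, c) is the Pearson correlation of f's
    values with c's membership indicator. Each feature goes to its argmax-r
    cluster (ties broken by lowest cluster id); within a cluster features
    are ranked by descending r and the ``top_n`` best returned.
    Zero-variance features are excluded with a warning; clusters with fewer
    than 2 events are excluded with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray([str(l) for l in labels])
    feature_names = list(feature_names)
    if X.shape[1] != len(feature_names):
        raise ValueError("feature_names length must match X columns")
    clusters = sorted(set(labels.tolist()))
    if len(clusters) < 2:
        raise ValueError("marker_finder needs at least 2 clusters")
    keep_clusters = []
    for c in clusters:
        if (labels == c).sum() < 2:
            warnings.warn(f"cluster {c!r} has < 2 events; excluded", stacklevel=2)
        else:
            keep_clusters.append(c)
    sd = X.std(axis=0)
    if np.all(sd == 0):
        warnings.warn("all features constant; no markers found", stacklevel=2)
        return []
    keep_feat = np.where(sd > 0)[0]
    for j in np.where(sd == 0)[0]:
        warnings.warn(
            f"feature {feature_names[j]!r} has zero variance; excluded",
            stacklevel=2,
        )
    # correlation of every kept feature with every cluster indicator,
    # vectorized: corr(f, ind) = cov / (sd_f * sd_ind)
    n = X.shape[0]
    Xc = X[:, keep_feat] - X[:, keep_feat].mean(axis=0)
    rmat = np.empty((len(keep_feat), len(keep_clusters)))
    for k, c in enumerate(keep_clusters):
        ind = (labels == c).astype(np.float64)
        indc = ind - ind.mean()
        denom = np.sqrt((Xc**2).sum(axis=0) * (indc**2).sum())
        rmat[:, k] = (Xc * indc[:, None]).sum(axis=0) / denom
    best = rmat.argmax(axis=1)  # argmax ties: lowest index = lowest cluster id
    out: list[MarkerAssignment] = []
    for k, c in enumerate(keep_clusters):
        members = np.where(best == k)[0]
        order = members[np.argsort(-rmat[members, k], kind="stable")]
        for rank, fi in enumerate(order[:top_n], start=1):
            out.append(
                MarkerAssignment(
                    feature=feature_names[keep_feat[fi]],
                    cluster=c,
                    r=float(rmat[fi, k]),
                    rank=rank,
                )
            )
    return out


def read_reference_profiles(path: str) -> list[ReferenceProfile]:
    """Load label x feature centroids from a CSV/TSV (labels in column 1)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return [
        ReferenceProfile(
            label=str(idx), centroid=row.to_dict(), n_cells=0
        )
        for idx, row in df.iterrows()
    ]


def label_transfer(
    X: np.ndarray,
    feature_names: Sequence[str],
    reference: Sequence[ReferenceProfile],
    name_map: Mapping[str, str] | None = None,
    min_correlation: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each query event the best-correlated reference label.

    ``name_map`` renames query features (e.g. protein to gene symbol) before
    intersecting with the reference feature space; at least 3 shared
    features are required. Each event's vector over shared features is
    compared with every centroid by Pearson correlation; the argmax label
    wins (ties broken lexicographically, with a warning), and events whose
    best correlation falls below ``min_correlation`` are "unassigned".

    Returns (labels, scores) arrays over events.
    """
    name_map = dict(name_map or {})
    mapped = [name_map.get(f, f) for f in feature_names]
    ref_feats = set()
    for p in reference:
        ref_feats.update(p.centroid.keys())
    shared = [f for f in mapped if f in ref_feats]
    # deduplicate, preserving order
    shared = list(dict.fromkeys(shared))
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared features for label transfer; query offers "
            f"{sorted(set(mapped))}, reference offers {sorted(ref_feats)}"
        )
    q_idx = [mapped.index(f) for f in shared]
    Q = np.asarray(X, dtype=np.float64)[:, q_idx]
    ref_sorted = sorted(reference, key=lambda p: p.label)
    C = np.array([[p.centroid[f] for f in shared] for p in ref_sorted])
    ref_labels = np.array([p.label for p in ref_sorted])

    # rowwise Pearson correlation between each event and each centroid
    Qc = Q - Q.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    qn = np.linalg.norm(Qc, axis=1, keepdims=True)
    cn = np.linalg.norm(Cc, axis=1, keepdims=True)
    qn[qn == 0] = np.inf  # constant event vector: correlation 0 everywhere
    cn[cn == 0] = np.inf
    R = (Qc / qn) @ (Cc / cn).T

    best = R.argmax(axis=1)  # ties: lowest index = lexicographically first label
    scores = R[np.arange(R.shape[0]), best]
    ties = (R == scores[:, None]).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} event(s) tied between reference centroids; "
            "broken lexicographically",
            stacklevel=2,
        )
    labels = ref_labels[best].astype(object)
    labels[scores < min_correlation] = "unassigned"
    return np.asarray(labels, dtype=object), scores
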