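"""Seeded wrappers over the standard single-cell embedding/clustering stack.

The imputed protein matrix behaves like a dense single-cell expression
matrix, so the usual scanpy pipeline applies directly: standardize features,
PCA, k-nearest-neighbour graph, Leiden community detection, and a 2-D UMAP
embedding — every stage seeded for reproducibility. Cluster labels are
relabelled to contiguous integers from 0 and written back into the event
metadata. Sub-clustering reruns the same stack on one cluster's events,
namespacing child labels as ``parent.child``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import scanpy as sc

__all__ = ["ClusterResult", "embed_and_cluster", "subcluster"]


@dataclass
class ClusterResult:
    """Leiden labels plus the embedding they were computed on."""

    labels: np.ndarray  # per-event cluster id (str, contiguous ints or parent.child)
    resolution: float
    n_neighbors: int
    seed: int
    embedding: np.ndarray | None = None  # events x 2 UMAP coordinates


def _contiguous(labels: np.ndarray) -> np.ndarray:
    # relabel by first appearance in sorted-by-size order for stability
    vals, counts = np.unique(labels, return_counts=True)
    order = vals[np.argsort(-counts, kind="stable")]
    mapping = {v: str(i) for i, v in enumerate(order)}
    return np.array([mapping[v] for v in labels])


def embed_and_cluster(
    adata: ad.AnnData,
    n_pcs: int = 30,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    umap: bool = True,
) -> ClusterResult:
    """PCA -> kNN graph -> Leiden -> UMAP on the annotated matrix, in place.

    Features are standardized (mean 0, sd 1) for the embedding only; the
    stored X is untouched. ``n_pcs`` is clamped (with a warning) when it
    reaches the feature count. Labels land in ``adata.obs['leiden']`` and
    coordinates in ``adata.obsm['X_umap']``.
    """
    if adata.n_obs < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} events, have {adata.n_obs}"
        )
    work = adata.copy()
    sc.pp.scale(work)
    max_pcs = min(work.n_vars, work.n_obs) - 1
    if n_pcs > max_pcs:
        warnings.warn(
            f"n_pcs={n_pcs} clamped to {max_pcs} (feature/event limit)",
            stacklevel=2,
        )
        n_pcs = max_pcs
    sc.pp.pca(work, n_comps=n_pcs, random_state=seed)
    sc.pp.neighbors(work, n_neighbors=n_neighbors, random_state=seed)
    sc.tl.leiden(
        work,
        resolution=resolution,
        random_state=seed,
        flavor="leidenalg",
    )
    labels = _contiguous(work.obs["leiden"].to_numpy())
    embedding = None
    if umap:
        sc.tl.umap(work, random_state=seed)
        embedding = np.asarray(work.obsm["X_umap"])
        adata.obsm["X_umap"] = embedding
    adata.obs["leiden"] = pd_categorical(labels)
    adata.obsm["X_pca"] = np.asarray(work.obsm["X_pca"])
    return ClusterResult(
        labels=labels,
        resolution=resolution,
        n_neighbors=n_neighbors,
        seed=seed,
        embedding=embedding,
    )


def pd_categorical(labels: np.ndarray):
    import pandas as pd

    # numeric-aware category order so '10' sorts after '2'
    def keyfn(v: str):
        parts = v.split(".")
        return tuple(int(p) if p.isdigit() else p for p in parts)

    cats = sorted(set(labels.tolist()), key=keyfn)
    return pd.Categorical(labels, categories=cats)


def subcluster(
    adata: ad.AnnData,
    parent_label: str,
    n_pcs: int = 30,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    label_key: str = "leiden",
    umap: bool = False,
) -> ClusterResult:
    """Recluster one cluster's events; children labelled ``parent.child``.

    Labels outside the parent cluster are never modified. Results are
    written to ``adata.obs['<label_key>_sub']``.
    """
    parent_label = str(parent_label)
    mask = adata.obs[label_key].astype(str).to_numpy() == parent_label
    n_sub = int(mask.sum())
    if n_sub == 0:
        raise ValueError(f"cluster {parent_label!r} is empty")
    if n_sub < n_neighbors + 1:
        raise ValueError(
            f"cluster {parent_label!r} has {n_sub} events; "
            f"need at least n_neighbors+1={n_neighbors + 1} to subcluster"
        )
    sub = adata[mask].copy()
    res = embed_and_cluster(
        sub, n_pcs=n_pcs, n_neighbors=n_neighbors,
        resolution=resolution, seed=seed, umap=umap,
    )
    child = np.array([f"{parent_label}.{c}" for c in res.labels])
    full = adata.obs[label_key].astype(str).to_numpy().copy()
    full[mask] = child
    adata.obs[f"{label_key}_sub"] = pd_categorical(full)
    res.labels = child
    return res
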