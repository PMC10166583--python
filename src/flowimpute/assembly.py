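"""Assembling and exporting the final annotated events x features object.

The prediction substrate is either a pool of held-out validation events
(default 10 000 per capture file, concatenated in file order) or every event
of a user-supplied backbone-only reference file. Imputed marker columns and
any passthrough channels are attached, and the result is held as an AnnData
object whose feature order is fixed: backbone (transformed) block, then
imputed block, then passthrough block. Every event stays traceable to its
(source file, original event index). Export formats: h5ad, feather, csv.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .fcsio import EventMatrix
from .imputation import TrainValSplit, derive_seed, transform_backbone
from .transforms import TransformSpec, apply_transform

__all__ = [
    "pool_events",
    "use_reference",
    "assemble",
    "export",
    "import_annotated",
]

FEATURE_ROLES = ("backbone_transformed", "imputed", "passthrough")


def pool_events(
    files: Sequence[EventMatrix],
    splits: Mapping[str, TrainValSplit],
    backbone_names: Sequence[str],
    spec: TransformSpec,
    n_per_file: int = 10_000,
    seed: int = 0,
    zscore: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sample validation events per file and concatenate their backbones.

    From each file's validation half, ``n_per_file`` events are sampled
    without replacement (all of them, with a warning, if fewer exist) and
    their transformed backbone rows concatenated in file order. Returns the
    pooled backbone matrix and per-event metadata with ``source_file`` and
    ``original_event_index``.
    """
    blocks: list[np.ndarray] = []
    meta_rows: list[pd.DataFrame] = []
    for m in files:
        key = (m.source_path or "<memory>").rsplit("/", 1)[-1]
        split = splits[key]
        n_avail = split.val_idx.size
        take = n_per_file
        if n_avail < n_per_file:
            warnings.warn(
                f"{key}: only {n_avail} validation events available, "
                f"requested {n_per_file}; taking all",
                stacklevel=2,
            )
            take = n_avail
        rng = np.random.default_rng(derive_seed(seed, key, "pool"))
        chosen = np.sort(rng.choice(split.val_idx, size=take, replace=False))
        bb = transform_backbone(m, backbone_names, spec, zscore=zscore)
        blocks.append(bb[chosen])
        meta_rows.append(
            pd.DataFrame(
                {"source_file": key, "original_event_index": chosen}
            )
        )
    pooled = np.vstack(blocks)
    meta = pd.concat(meta_rows, ignore_index=True)
    return pooled, meta


def use_reference(
    reference: EventMatrix,
    backbone_names: Sequence[str],
    spec: TransformSpec,
    zscore: bool = False,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, list[str]]:
    """All events of a separate reference file as the prediction substrate.

    No sampling: every reference event becomes a row of the final object.
    Channels of the reference outside the backbone are carried along as
    passthrough features (transformed per their role).

    Returns the transformed backbone matrix, event metadata, the
    passthrough block, and the passthrough feature names.
    """
    for name in backbone_names:
        reference.resolve_channel(name)  # raises KeyError if missing
    bb = transform_backbone(reference, backbone_names, spec, zscore=zscore)
    key = (reference.source_path or "<memory>").rsplit("/", 1)[-1]
    meta = pd.DataFrame(
        {
            "source_file": key,
            "original_event_index": np.arange(reference.n_events),
        }
    )
    bb_idx = {reference.resolve_channel(n) for n in backbone_names}
    pass_cols, pass_names = [], []
    for i, ch in enumerate(reference.channels):
        if i in bb_idx:
            continue
        pass_cols.append(
            apply_transform(reference.data[:, i], spec, ch.short_name, ch.role)
        )
        pass_names.append(ch.short_name)
    passthrough = (
        np.column_stack(pass_cols)
        if pass_cols
        else np.empty((reference.n_events, 0))
    )
    return bb, meta, passthrough, pass_names


def assemble(
    backbone: np.ndarray,
    backbone_names: Sequence[str],
    imputed: np.ndarray,
    marker_names: Sequence[str],
    event_meta: pd.DataFrame,
    passthrough: np.ndarray | None = None,
    passthrough_names: Sequence[str] | None = None,
    run_meta: Mapping[str, object] | None = None,
) -> ad.AnnData:
    """Build the final AnnData: backbone block, imputed block, passthrough block."""
    passthrough_names = list(passthrough_names or [])
    if passthrough is None:
        passthrough = np.empty((backbone.shape[0], 0))
    X = np.hstack([backbone, imputed, passthrough]).astype(np.float32)
    var = pd.DataFrame(
        {
            "feature_role": (
                ["backbone_transformed"] * len(backbone_names)
                + ["imputed"] * len(marker_names)
                + ["passthrough"] * len(passthrough_names)
            )
        },
        index=pd.Index(
            list(backbone_names) + list(marker_names) + passthrough_names,
            name="feature",
        ),
    )
    obs = event_meta.copy()
    obs.index = pd.Index([str(i) for i in range(len(obs))], name="event")
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["run_meta"] = dict(run_meta or {})
    return adata


def export(adata: ad.AnnData, path: str, fmt: str = "h5ad") -> str:
    """Write the annotated matrix as h5ad, feather, or csv.

    The flat formats carry event metadata in ``meta_``-prefixed columns
    ahead of the feature columns; re-import reproduces X exactly.
    """
    if fmt == "h5ad":
        adata.write_h5ad(path)
        return path
    df = pd.DataFrame(
        np.asarray(adata.X, dtype=np.float32),
        columns=adata.var_names,
    )
    meta = adata.obs.reset_index(drop=True)
    meta.columns = [f"meta_{c}" for c in meta.columns]
    flat = pd.concat([meta, df], axis=1)
    if fmt == "feather":
        flat.to_feather(path)
    elif fmt == "csv":
        flat.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported export format {fmt!r} (h5ad, feather, csv)")
    return path


def import_annotated(path: str, fmt: str = "h5ad") -> ad.AnnData:
    """Read back an exported object (inverse of :func:`export`)."""
    if fmt == "h5ad":
        return ad.read_h5ad(path)
    if fmt == "feather":
        flat = pd.read_feather(path)
    elif fmt == "csv":
        flat = pd.read_csv(path)
    else:
        raise ValueError(f"unsupported import format {fmt!r}")
    meta_cols = [c for c in flat.columns if c.startswith("meta_")]
    obs = flat[meta_cols].copy()
    obs.columns = [c[len("meta_") :] for c in meta_cols]
    obs.index = pd.Index([str(i) for i in range(len(obs))], name="event")
    feats = [c for c in flat.columns if not c.startswith("meta_")]
    X = flat[feats].to_numpy(dtype=np.float32)
    return ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(feats, name="feature"))
    )
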