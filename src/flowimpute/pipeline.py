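"""Full-run orchestration: read -> harmonize -> transform -> split -> fit ->
validate -> predict -> (isotype-correct) -> assemble -> export.

:func:`run_pipeline` executes the whole workflow from a :class:`RunConfig`;
the stage functions it calls are also exposed individually so the command
line can run the same computation stepwise with identical seeds (and hence
bit-identical output).

Isotype convention: a capture annotated with ``marker_name ==
"isotype_<group>"`` is the control for that group; every other marker in
the group is corrected against the control's imputed column.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import __version__
from .assembly import assemble, export, pool_events, use_reference
from .background import IsotypeAssignment, correct_background
from .config import RunConfig, load_annotation
from .fcsio import EventMatrix, harmonize_channels, read_fcs
from .imputation import derive_seed, impute_all, split_events
from .transforms import TransformSpec

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "isotype_assignments", "prepare_inputs"]


def isotype_assignments(annotation: pd.DataFrame) -> list[IsotypeAssignment]:
    """Marker -> control pairings implied by the annotation's isotype groups."""
    out = []
    for _, row in annotation.iterrows():
        g = str(row.get("isotype_group", "") or "")
        name = str(row["marker_name"])
        control = f"isotype_{g}"
        if g and name != control:
            out.append(IsotypeAssignment(name, control, group=g))
    return out


def prepare_inputs(
    config: RunConfig,
) -> tuple[list[EventMatrix], pd.DataFrame, dict]:
    """Read and harmonize every annotated FCS file; compute per-file splits."""
    config.validate_paths()
    ann_path = Path(config.data_dir) / config.annotation
    if not ann_path.exists():
        ann_path = Path(config.annotation)
    annotation = load_annotation(ann_path)
    files = []
    for fname in annotation["file"].unique():
        p = Path(config.data_dir) / fname
        if not p.exists():
            p = Path(fname)
        files.append(read_fcs(p))
    files = harmonize_channels(files, config.backbone)
    splits = {
        (m.source_path or "<memory>").rsplit("/", 1)[-1]: split_events(
            m.n_events,
            config.split_fraction,
            derive_seed(
                config.seed, (m.source_path or "<memory>").rsplit("/", 1)[-1], "split"
            ),
        )
        for m in files
    }
    return files, annotation, splits


def run_pipeline(config: RunConfig) -> tuple[ad.AnnData, dict]:
    """Execute the whole workflow; returns the final AnnData and a QC report.

    The QC report carries per-marker validation MSE/MAE, the background fit
    report, per-file event counts, and the seeds used, and is written as
    JSON next to the output file.
    """
    files, annotation, splits = prepare_inputs(config)
    spec: TransformSpec = config.transform

    ann_map: dict[str, list[tuple[str, str]]] = {}
    for _, row in annotation.iterrows():
        ann_map.setdefault(str(row["file"]), []).append(
            (str(row["infinity_channel"]), str(row["marker_name"]))
        )

    passthrough = None
    passthrough_names: list[str] = []
    if config.mode == "pooling":
        backbone, event_meta = pool_events(
            files,
            splits,
            config.backbone,
            spec,
            n_per_file=config.n_per_file,
            seed=config.seed,
            zscore=config.zscore,
        )
    else:
        ref_path = Path(config.data_dir) / config.reference_fcs
        if not ref_path.exists():
            ref_path = Path(config.reference_fcs)
        reference = read_fcs(ref_path)
        backbone, event_meta, passthrough, passthrough_names = use_reference(
            reference, config.backbone, spec, zscore=config.zscore
        )

    models, imputed, marker_names = impute_all(
        files,
        ann_map,
        config.backbone,
        backbone,
        spec=spec,
        hyperparams=config.regression,
        fraction=config.split_fraction,
        run_seed=config.seed,
        zscore=config.zscore,
        min_events=config.min_events,
        splits=splits,
    )

    bg_report: list[dict] = []
    if config.isotype_correction:
        assigns = [
            a for a in isotype_assignments(annotation)
            if a.marker_name in marker_names
            and a.isotype_marker_name in marker_names
        ]
        if assigns:
            imputed, fits = correct_background(imputed, marker_names, assigns)
            bg_report = [vars(f) for f in fits]

    run_meta = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "zscore": config.zscore,
        "isotype_correction": config.isotype_correction,
        "transform_kind": spec.kind,
        "split_fraction": config.split_fraction,
        "n_per_file": config.n_per_file,
    }
    adata = assemble(
        backbone,
        config.backbone,
        imputed,
        marker_names,
        event_meta,
        passthrough=passthrough,
        passthrough_names=passthrough_names,
        run_meta=run_meta,
    )

    qc = {
        "markers": [
            {
                "marker": m.marker_name,
                "source_file": m.source_file.rsplit("/", 1)[-1],
                "val_mse": m.val_mse,
                "val_mae": m.val_mae,
                "n_train": int(m.split.train_idx.size),
                "n_val": int(m.split.val_idx.size),
                "seed": m.seed,
                "warnings": m.warnings,
            }
            for m in models
        ],
        "background_fits": bg_report,
        "event_counts": {
            (m.source_path or "<memory>").rsplit("/", 1)[-1]: m.n_events
            for m in files
        },
        "pooled_events": int(adata.n_obs),
        "run_meta": run_meta,
    }

    out = Path(config.output)
    try:
        export(adata, str(out), config.output_format)
        out.with_suffix(".qc.json").write_text(json.dumps(qc, indent=2))
    except Exception:
        # never leave partial outputs behind
        for p in (out, out.with_suffix(".qc.json")):
            p.unlink(missing_ok=True)
        raise
    logger.info("wrote %s (%d events x %d features)", out, adata.n_obs, adata.n_vars)
    return adata, qc
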