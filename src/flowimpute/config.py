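"""Run configuration: everything a full pipeline run needs, from YAML or code.

A run is described by the annotation table (which file carries which
exploratory marker, and its isotype group), the shared backbone channel
list, transform and regression settings, the prediction-substrate mode
(pooling vs. a separate reference FCS), and seeds. Defaults encode the
standard workflow: logicle scale, 50/50 train/validation split, 10 000
pooled validation events per file, z-score off, isotype correction on when
isotype groups are annotated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .imputation import XgbParams
from .transforms import TransformSpec

__all__ = ["RunConfig", "load_annotation", "setup_logging"]


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )


@dataclass
class RunConfig:
    """Validated settings for one pipeline run."""

    data_dir: str = "."
    annotation: str = "annotation.csv"
    backbone: list[str] = field(default_factory=list)
    transform: TransformSpec = field(default_factory=TransformSpec)
    regression: XgbParams = field(default_factory=XgbParams)
    split_fraction: float = 0.5
    zscore: bool = False
    isotype_correction: bool = True
    mode: str = "pooling"  # pooling | reference
    reference_fcs: str | None = None
    n_per_file: int = 10_000
    min_events: int = 300
    seed: int = 0
    output: str = "infinity_flow.h5ad"
    output_format: str = "h5ad"

    def __post_init__(self) -> None:
        if self.mode not in ("pooling", "reference"):
            raise ValueError(f"mode must be 'pooling' or 'reference', got {self.mode!r}")
        if self.mode == "reference" and not self.reference_fcs:
            raise ValueError("reference mode requires reference_fcs")
        if self.mode == "pooling" and self.reference_fcs:
            raise ValueError("pooling mode must not set reference_fcs (modes are exclusive)")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.output_format not in ("h5ad", "feather", "csv"):
            raise ValueError(f"unsupported output format {self.output_format!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        tf = raw.pop("transform", {})
        if isinstance(tf, dict):
            raw["transform"] = TransformSpec(
                kind=tf.get("kind", "logicle"),
                T=float(tf.get("T", 262144.0)),
                M=float(tf.get("M", 4.5)),
                A=float(tf.get("A", 0.0)),
                logicle_w=tf.get("W"),
                cofactor=float(tf.get("cofactor", 150.0)),
                per_channel=tf.get("per_channel", {}),
            )
        rg = raw.pop("regression", {})
        if isinstance(rg, dict):
            raw["regression"] = XgbParams(
                n_estimators=int(rg.get("n_estimators", 500)),
                learning_rate=float(rg.get("learning_rate", 0.05)),
                max_depth=int(rg.get("max_depth", 6)),
                subsample=float(rg.get("subsample", 1.0)),
                n_jobs=int(rg.get("n_jobs", 1)),
            )
        return cls(**raw)

    def validate_paths(self) -> None:
        ann = Path(self.data_dir) / self.annotation
        if not ann.exists() and not Path(self.annotation).exists():
            raise FileNotFoundError(f"annotation table not found: {ann}")
        if self.reference_fcs:
            ref = Path(self.data_dir) / self.reference_fcs
            if not ref.exists() and not Path(self.reference_fcs).exists():
                raise FileNotFoundError(f"reference FCS not found: {ref}")


def load_annotation(path: str | Path) -> pd.DataFrame:
    """Read the annotation CSV (columns: file, infinity_channel, marker_name,
    optional isotype_group)."""
    df = pd.read_csv(path)
    required = {"file", "infinity_channel", "marker_name"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if "isotype_group" not in df.columns:
        df["isotype_group"] = ""
    df["isotype_group"] = df["isotype_group"].fillna("")
    if df["marker_name"].duplicated().any():
        dups = df.loc[df["marker_name"].duplicated(), "marker_name"].tolist()
        logging.getLogger(__name__).warning(
            "duplicate marker names in annotation: %s (will be suffixed)", dups
        )
    return df
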