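"""Synthetic multi-file flow-cytometry panels with known ground truth.

Real Infinity Flow inputs are dozens of FCS captures sharing a backbone
panel, each adding one exploratory channel on a common fluorochrome. This
generator emulates that design so every pipeline stage is testable without
instrument data: events are drawn from a mixture of multivariate-normal
populations on the raw intensity scale (clipped at zero by default, as a
digital cytometer reports), each exploratory channel is a known link
function of the backbone plus Gaussian noise plus an optional planted
isotype background, and isotype-control files carry the background signal
alone. Because the links, noise levels, population labels, and isotype
slopes are known, the generator can also state the theoretically attainable
imputation correlation for each marker — the yardstick the imputation tests
measure against.

Derived backbone channels (a link of the base channels plus noise) support
the surrogate-backbone benchmark: a panel where some truly "measured"
backbone channels are known functions of the others, so predicting them
from the rest has a computable ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fcsio import ChannelDescriptor, EventMatrix, write_fcs

__all__ = [
    "LinkSpec",
    "MarkerSpec",
    "SyntheticPanelSpec",
    "sample_backbone",
    "generate_file",
    "generate_panel",
    "attainable_r",
    "default_marker_panel",
    "surrogate_panel_spec",
]


@dataclass(frozen=True)
class LinkSpec:
    """A known function of the backbone generating one signal.

    kinds
    -----
    linear       ``scale * x[ch0] + intercept``
    logistic     ``scale / (1 + exp(-(x[ch0] - center) / width)) + intercept``
                 (switch-like: on in high-expressing populations only)
    interaction  ``scale * x[ch0] * x[ch1] / center + intercept``
    """

    kind: str
    channels: tuple[int, ...]
    scale: float = 1.0
    intercept: float = 0.0
    center: float = 1.0
    width: float = 1.0

    def __call__(self, backbone: np.ndarray) -> np.ndarray:
        x0 = backbone[:, self.channels[0]]
        if self.kind == "linear":
            return self.scale * x0 + self.intercept
        if self.kind == "logistic":
            return (
                self.scale / (1.0 + np.exp(-(x0 - self.center) / self.width))
                + self.intercept
            )
        if self.kind == "interaction":
            x1 = backbone[:, self.channels[1]]
            return self.scale * x0 * x1 / self.center + self.intercept
        raise ValueError(f"unknown link kind {self.kind!r}")


@dataclass(frozen=True)
class MarkerSpec:
    """One exploratory channel: its link, noise, and planted background."""

    name: str
    link: LinkSpec
    noise_sd: float = 0.0
    isotype_beta: float = 0.0
    isotype_group: str = ""


@dataclass
class SyntheticPanelSpec:
    """Generative description of a test panel.

    ``backbone_means`` is populations x base-backbone; ``backbone_sds`` the
    matching per-population standard deviations (channels independent given
    the population — the population structure itself supplies the
    between-channel correlation that imputation exploits).
    ``derived_backbone`` entries ``(name, link, noise_sd)`` append extra
    backbone channels computed from the base ones. Each isotype group maps
    to the link generating its nonspecific background signal.
    """

    backbone_names: list[str]
    population_weights: np.ndarray
    backbone_means: np.ndarray
    backbone_sds: np.ndarray
    markers: list[MarkerSpec] = field(default_factory=list)
    derived_backbone: list[tuple[str, LinkSpec, float]] = field(default_factory=list)
    isotype_links: dict[str, LinkSpec] = field(default_factory=dict)
    isotype_noise_sd: float = 0.0
    n_events_per_file: int = 20_000
    seed: int = 0
    clip_negative: bool = True
    exploratory_channel: str = "PE-A"

    def __post_init__(self) -> None:
        self.population_weights = np.asarray(self.population_weights, float)
        self.backbone_means = np.atleast_2d(np.asarray(self.backbone_means, float))
        self.backbone_sds = np.atleast_2d(np.asarray(self.backbone_sds, float))
        if not np.isclose(self.population_weights.sum(), 1.0):
            raise ValueError("population weights must sum to 1")
        if (self.backbone_sds < 0).any():
            raise ValueError("backbone sds must be non-negative")
        if self.backbone_means.shape != self.backbone_sds.shape:
            raise ValueError("means and sds must have matching shapes")
        if self.backbone_means.shape[0] != self.population_weights.size:
            raise ValueError("one mean row per population required")
        if self.backbone_means.shape[1] != len(self.backbone_names):
            raise ValueError("one mean column per base backbone channel required")
        for m in self.markers:
            if m.noise_sd < 0:
                raise ValueError(f"marker {m.name}: noise sd must be >= 0")

    @property
    def all_backbone_names(self) -> list[str]:
        return self.backbone_names + [n for n, _, _ in self.derived_backbone]


def sample_backbone(
    spec: SyntheticPanelSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n events: (full backbone matrix incl. derived channels, population ids)."""
    pops = rng.choice(spec.population_weights.size, size=n, p=spec.population_weights)
    base = rng.normal(
        loc=spec.backbone_means[pops], scale=spec.backbone_sds[pops]
    )
    if spec.clip_negative:
        base = np.clip(base, 0.0, None)
    cols = [base]
    for _, link, noise_sd in spec.derived_backbone:
        col = link(base) + rng.normal(0.0, noise_sd, size=n)
        if spec.clip_negative:
            col = np.clip(col, 0.0, None)
        cols.append(col[:, None])
    return np.hstack(cols), pops


def _channels(spec: SyntheticPanelSpec, exploratory: str | None) -> list[ChannelDescriptor]:
    chans = [
        ChannelDescriptor(short_name=n, range=262144.0, role="backbone")
        for n in spec.all_backbone_names
    ]
    if exploratory:
        chans.append(
            ChannelDescriptor(short_name=exploratory, range=262144.0, role="infinity")
        )
    return chans


def generate_file(
    spec: SyntheticPanelSpec, marker: MarkerSpec | None, seed: int
) -> tuple[EventMatrix, pd.DataFrame]:
    """One capture file (or backbone-only reference when ``marker`` is None).

    Returns the EventMatrix and its truth table (population id, true marker
    value before noise/background, background component).
    """
    rng = np.random.default_rng(seed)
    n = spec.n_events_per_file
    backbone, pops = sample_backbone(spec, n, rng)
    truth = pd.DataFrame({"population": pops})
    if marker is None:
        em = EventMatrix(
            data=backbone,
            channels=_channels(spec, None),
            keywords={"PANEL": "synthetic-reference"},
        )
        return em, truth
    signal = marker.link(backbone[:, : len(spec.backbone_names)])
    background = np.zeros(n)
    if marker.isotype_group and marker.isotype_beta != 0.0:
        iso_link = spec.isotype_links[marker.isotype_group]
        background = marker.isotype_beta * iso_link(
            backbone[:, : len(spec.backbone_names)]
        )
    observed = signal + background + rng.normal(0.0, marker.noise_sd, size=n)
    if spec.clip_negative:
        observed = np.clip(observed, 0.0, None)
    truth["true_marker"] = signal
    truth["background"] = background
    data = np.hstack([backbone, observed[:, None]])
    em = EventMatrix(
        data=data,
        channels=_channels(spec, spec.exploratory_channel),
        keywords={"PANEL": "synthetic", "MARKER": marker.name},
    )
    return em, truth


def generate_isotype_file(
    spec: SyntheticPanelSpec, group: str, seed: int
) -> tuple[EventMatrix, pd.DataFrame]:
    """An isotype-control capture: exploratory channel carries background only."""
    rng = np.random.default_rng(seed)
    n = spec.n_events_per_file
    backbone, pops = sample_backbone(spec, n, rng)
    iso = spec.isotype_links[group](backbone[:, : len(spec.backbone_names)])
    observed = iso + rng.normal(0.0, spec.isotype_noise_sd, size=n)
    if spec.clip_negative:
        observed = np.clip(observed, 0.0, None)
    data = np.hstack([backbone, observed[:, None]])
    em = EventMatrix(
        data=data,
        channels=_channels(spec, spec.exploratory_channel),
        keywords={"PANEL": "synthetic-isotype", "GROUP": group},
    )
    truth = pd.DataFrame({"population": pops, "background": iso})
    return em, truth


def generate_panel(
    spec: SyntheticPanelSpec, out_dir: str | Path
) -> tuple[list[Path], pd.DataFrame]:
    """Write the whole panel to ``out_dir``: FCS files, truth TSVs, annotation CSV.

    One FCS file per marker, one per isotype group, plus ``annotation.csv``
    mapping files to markers and isotype groups. Deterministic per
    ``spec.seed`` (same seed, byte-identical files).

    Returns the FCS paths and the annotation table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .imputation import derive_seed  # local import to avoid cycle

    paths: list[Path] = []
    rows = []
    for m in spec.markers:
        em, truth = generate_file(spec, m, derive_seed(spec.seed, "file", m.name))
        p = out_dir / f"{m.name}.fcs"
        write_fcs(em, p)
        truth.to_csv(out_dir / f"{m.name}.truth.tsv", sep="\t", index=False)
        paths.append(p)
        rows.append(
            {
                "file": p.name,
                "infinity_channel": spec.exploratory_channel,
                "marker_name": m.name,
                "isotype_group": m.isotype_group,
            }
        )
    for group in spec.isotype_links:
        em, truth = generate_isotype_file(
            spec, group, derive_seed(spec.seed, "isotype", group)
        )
        p = out_dir / f"isotype_{group}.fcs"
        write_fcs(em, p)
        truth.to_csv(out_dir / f"isotype_{group}.truth.tsv", sep="\t", index=False)
        paths.append(p)
        rows.append(
            {
                "file": p.name,
                "infinity_channel": spec.exploratory_channel,
                "marker_name": f"isotype_{group}",
                "isotype_group": group,
            }
        )
    annotation = pd.DataFrame(rows)
    annotation.to_csv(out_dir / "annotation.csv", index=False)
    return paths, annotation


def attainable_r(
    spec: SyntheticPanelSpec,
    marker: MarkerSpec | tuple[str, LinkSpec, float],
    n_mc: int = 100_000,
) -> float:
    """Theoretical ceiling on Pearson r between any backbone predictor and the marker.

    With additive independent noise, the best possible correlation between a
    function of the backbone and the observed marker is
    ``sd(link) / sqrt(sd(link)^2 + noise_sd^2)``; sd(link) is estimated by
    Monte-Carlo from the generator itself.
    """
    if isinstance(marker, tuple):
        name, link, noise_sd = marker
    else:
        link, noise_sd = marker.link, marker.noise_sd
    rng = np.random.default_rng(spec.seed + 987_001)
    pops = rng.choice(
        spec.population_weights.size, size=n_mc, p=spec.population_weights
    )
    base = rng.normal(spec.backbone_means[pops], spec.backbone_sds[pops])
    if spec.clip_negative:
        base = np.clip(base, 0.0, None)
    s = float(np.std(link(base)))
    return s / np.sqrt(s**2 + float(noise_sd) ** 2)


# ---------------------------------------------------------------------------
# ready-made panels
# ---------------------------------------------------------------------------


def default_marker_panel(
    n_files: int = 3,
    n_events_per_file: int = 20_000,
    seed: int = 0,
    with_isotype: bool = False,
    isotype_betas: Sequence[float] | None = None,
) -> SyntheticPanelSpec:
    """A small immunophenotyping-like panel: 8 backbone channels, 3 populations.

    Backbone intensities sit in the digital cytometer's typical decades
    (hundreds to tens of thousands); each file's exploratory marker is a
    distinct link of the backbone with noise at a third of the signal sd
    (signal-to-noise 3, an optimistic but realistic stained-marker regime).
    """
    rng = np.random.default_rng(seed)
    n_bb = 8
    names = [f"BB{i + 1}" for i in range(n_bb)]
    n_pop = 3
    means = rng.uniform(500.0, 30_000.0, size=(n_pop, n_bb))
    sds = 0.3 * means
    weights = np.array([0.5, 0.3, 0.2])
    kinds = ["linear", "logistic", "interaction"]
    markers = []
    # when isotype controls are requested, a panel with no background would
    # make correction a no-op; 0.3 is a moderate nonspecific-binding slope
    betas = list(isotype_betas or ([0.3] if with_isotype else []))
    for j in range(n_files):
        kind = kinds[j % len(kinds)]
        ch = j % n_bb
        if kind == "linear":
            link = LinkSpec("linear", (ch,), scale=1.5, intercept=200.0)
        elif kind == "logistic":
            c = float(means[:, ch].mean())
            link = LinkSpec(
                "logistic", (ch,), scale=20_000.0, center=c, width=c / 4, intercept=100.0
            )
        else:
            ch2 = (ch + 1) % n_bb
            c = float((means[:, ch] * means[:, ch2]).mean())
            link = LinkSpec("interaction", (ch, ch2), scale=10_000.0, center=c)
        # noise at a third of the marker's own signal sd (Monte-Carlo estimate)
        probe = SyntheticPanelSpec(
            backbone_names=names,
            population_weights=weights,
            backbone_means=means,
            backbone_sds=sds,
            seed=seed,
        )
        sd_link = float(
            np.std(link(sample_backbone(probe, 20_000, np.random.default_rng(seed + j))[0]))
        )
        markers.append(
            MarkerSpec(
                name=f"Marker{j + 1}",
                link=link,
                noise_sd=sd_link / 3.0,
                isotype_beta=(betas[j % len(betas)] if betas else 0.0),
                isotype_group=("IgG1" if with_isotype else ""),
            )
        )
    isotype_links = {}
    iso_noise = 0.0
    if with_isotype:
        # background rides on a backbone channel none of the marker links use
        iso_ch = n_bb - 1
        isotype_links["IgG1"] = LinkSpec("linear", (iso_ch,), scale=0.5, intercept=50.0)
        iso_noise = 0.05 * float(means[:, iso_ch].mean())
    return SyntheticPanelSpec(
        backbone_names=names,
        population_weights=weights,
        backbone_means=means,
        backbone_sds=sds,
        markers=markers,
        isotype_links=isotype_links,
        isotype_noise_sd=iso_noise,
        n_events_per_file=n_events_per_file,
        seed=seed,
    )


def surrogate_panel_spec(
    n_events: int = 20_000, seed: int = 0
) -> SyntheticPanelSpec:
    """A 21-channel backbone: 11 base channels plus 10 derived ones.

    The 10 derived channels are known links of the 11 base channels with
    independent noise, so predicting them from the base channels (the
    surrogate backbone) has a computable attainable correlation — the
    self-benchmark design for imputation accuracy.
    """
    rng = np.random.default_rng(seed)
    n_base = 11
    names = [f"BB{i + 1}" for i in range(n_base)]
    n_pop = 4
    means = rng.uniform(500.0, 30_000.0, size=(n_pop, n_base))
    sds = 0.3 * means
    weights = np.array([0.4, 0.3, 0.2, 0.1])
    probe = SyntheticPanelSpec(
        backbone_names=names,
        population_weights=weights,
        backbone_means=means,
        backbone_sds=sds,
        seed=seed,
    )
    probe_bb = sample_backbone(probe, 20_000, np.random.default_rng(seed + 77))[0]
    derived = []
    kinds = ["linear", "logistic", "interaction"]
    for j in range(10):
        kind = kinds[j % 3]
        ch = j % n_base
        if kind == "linear":
            link = LinkSpec("linear", (ch,), scale=1.2, intercept=300.0)
        elif kind == "logistic":
            c = float(means[:, ch].mean())
            link = LinkSpec(
                "logistic", (ch,), scale=15_000.0, center=c, width=c / 4, intercept=200.0
            )
        else:
            ch2 = (ch + 2) % n_base
            c = float((means[:, ch] * means[:, ch2]).mean())
            link = LinkSpec("interaction", (ch, ch2), scale=12_000.0, center=c)
        sd_link = float(np.std(link(probe_bb)))
        derived.append((f"HX{j + 1}", link, sd_link / 3.0))
    return SyntheticPanelSpec(
        backbone_names=names,
        population_weights=weights,
        backbone_means=means,
        backbone_sds=sds,
        derived_backbone=derived,
        n_events_per_file=n_events,
        seed=seed,
    )
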