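import numpy as np
import pytest

from flowimpute.fcsio import ChannelDescriptor, EventMatrix


@pytest.fixture
def small_matrix() -> EventMatrix:
    """A 1000 x 12 random event matrix with mixed channel roles."""
    rng = np.random.default_rng(42)
    channels = [
        ChannelDescriptor(short_name="FSC-A", role="scatter"),
        ChannelDescriptor(short_name="SSC-A", role="scatter"),
    ] + [
        ChannelDescriptor(
            short_name=f"FL{i}-A", stain_name=f"CD{i}", role="backbone"
        )
        for i in range(1, 11)
    ]
    data = rng.uniform(0, 262144, size=(1000, 12))
    return EventMatrix(
        data=data,
        channels=channels,
        keywords={"CYT": "SyntheticCytometer", "OPERATOR": "tester"},
    )


@pytest.fixture
def tiny_panel(tmp_path):
    """A 3-file synthetic panel (small n) on disk, with annotation."""
    from flowimpute.synthetic import default_marker_panel, generate_panel

    spec = default_marker_panel(
        n_files=3, n_events_per_file=1200, seed=7, with_isotype=True,
        isotype_betas=[0.3],
    )
    paths, annotation = generate_panel(spec, tmp_path / "panel")
    return spec, paths, annotation, tmp_path / "panel"
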