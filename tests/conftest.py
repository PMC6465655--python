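import numpy as np
import pytest

from nipt_trio.baseline import build_baseline
from nipt_trio.panel import Panel, generate_panel_layout
from nipt_trio.simulate import simulate_reference_cohort

SMALL_SIZES = {
    "1": 60_000_000,
    "2": 50_000_000,
    "3": 45_000_000,
    "4": 40_000_000,
    "X": 40_000_000,
    "Y": 20_000_000,
}


@pytest.fixture(scope="session")
def small_panel() -> Panel:
    """Compact 4-chromosome panel for fast unit tests."""
    hotspots = {
        "HBB": [("1", 5_000_000 + 200 * i, 5_000_000 + 200 * i + 120) for i in range(5)],
        "GJB2": [("2", 9_000_000 + 200 * i, 9_000_000 + 200 * i + 90) for i in range(5)],
    }
    return generate_panel_layout(
        SMALL_SIZES, n_backbone=400, backbone_length=100,
        hotspot_spec=hotspots, chrom_counts={"X": 50, "Y": 20},
    )


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    return simulate_reference_cohort(
        small_panel, n_samples=30, total_reads=1_000_000, dispersion=0.002, seed=42
    )


@pytest.fixture(scope="session")
def small_baseline(small_panel, small_cohort):
    return build_baseline(small_cohort, small_panel, median_interval="sample")


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
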