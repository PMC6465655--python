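import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nipt_trio.baseline import BaselineDB
from nipt_trio.cnv import (
    CNVError,
    Segment,
    call_cnvs,
    call_sample_cnvs,
    haarseg_breakpoints,
    haarseg_segment,
    region_z,
)
from nipt_trio.simulate import SampleTruth, simulate_region_counts


def dp_optimal_sse(x: np.ndarray, k: int) -> float:
    """Exhaustive dynamic program: minimal SSE of a k-segment constant fit."""
    n = len(x)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def sse(a, b):  # cost of segment [a, b)
        s = c1[b] - c1[a]
        return (c2[b] - c2[a]) - s * s / (b - a)

    cost = np.full((k + 1, n + 1), np.inf)
    cost[0, 0] = 0.0
    for j in range(1, k + 1):
        for b in range(j, n + 1):
            cost[j, b] = min(cost[j - 1, a] + sse(a, b) for a in range(j - 1, b))
    return float(cost[k, n])


def reconstruction_sse(x: np.ndarray, segments: list[Segment]) -> float:
    return sum(
        float(((x[s.start_index:s.end_index] - s.mean_z) ** 2).sum()) for s in segments
    )


class TestHaarSegmentation:
    def test_constant_vector_is_single_segment(self):
        segs = haarseg_segment(np.zeros(50))
        assert len(segs) == 1
        assert (segs[0].start_index, segs[0].end_index) == (0, 50)

    def test_noiseless_step_recovered_exactly(self):
        z = np.zeros(100)
        z[40:60] = 3.0
        assert haarseg_breakpoints(z) == [40, 60]
        segs = haarseg_segment(z)
        assert [(s.start_index, s.end_index) for s in segs] == [(0, 40), (40, 60), (60, 100)]
        assert segs[1].median_z == pytest.approx(3.0)

    def test_noisy_step_near_dp_optimum(self, rng):
        """SSE within 10% of the optimal 3-segment fit (DP oracle)."""
        z = np.zeros(100)
        z[40:60] = 3.0
        z = z + rng.normal(0, 0.5, size=100)
        segs = haarseg_segment(z)
        assert reconstruction_sse(z, segs) <= 1.10 * dp_optimal_sse(z, 3)

    def test_segments_partition_chromosome(self, rng):
        z = rng.normal(0, 1, size=157)
        segs = haarseg_segment(z)
        bounds = [(s.start_index, s.end_index) for s in segs]
        assert bounds[0][0] == 0 and bounds[-1][1] == 157
        assert all(a[1] == b[0] for a, b in zip(bounds, bounds[1:]))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_partition_property_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(0, 1, size=rng.integers(2, 120))
        segs = haarseg_segment(z)
        covered = sorted((s.start_index, s.end_index) for s in segs)
        assert covered[0][0] == 0 and covered[-1][1] == len(z)
        assert all(a[1] == b[0] for a, b in zip(covered, covered[1:]))

    def test_stricter_fdr_never_adds_breakpoints(self, rng):
        z = np.zeros(200)
        z[50:90] = 2.0
        z[140:160] = -1.5
        z = z + rng.normal(0, 0.6, size=200)
        counts = [
            len(haarseg_breakpoints(z, fdr_q=q)) for q in (0.1, 0.01, 0.001, 1e-5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_non_finite_input_rejected(self):
        with pytest.raises(CNVError, match="non-finite"):
            haarseg_breakpoints(np.array([0.0, np.nan, 1.0]))


class TestRegionZ:
    def test_depth_at_mean_gives_zero_z(self, small_panel, small_baseline, small_cohort):
        zs = region_z(small_cohort[0], small_baseline, small_panel)
        pooled = np.concatenate([zs[c] for c in ("1", "2", "3", "4")])
        assert abs(np.mean(pooled)) < 0.5

    def test_duplication_shifts_affected_regions(self, small_panel, small_baseline):
        truth = SampleTruth(0.2, "XX", cnvs=[("1", 0, 30_000_000, +1)])
        s = simulate_region_counts(small_panel, truth, 1_000_000, 0.002, seed=13)
        zs = region_z(s, small_baseline, small_panel)
        starts = small_panel.backbone_starts[small_panel.backbone_index("1")]
        affected = zs["1"][starts < 30_000_000]
        unaffected = zs["2"]
        assert affected.mean() > 2.0
        # the shared autosomal denominator slightly depresses the rest
        assert -1.5 < unaffected.mean() < 0.5


def _db_with_interval(lo=-1.0, hi=1.0):
    return BaselineDB(
        panel_checksum="", n_samples=2,
        region_mean=np.zeros(1), region_sd=np.ones(1),
        chrom_mean={}, chrom_sd={}, x_mean={}, x_sd={},
        y_median_mean=0, y_median_sd=0, y_mean_mean=0, y_mean_sd=0,
        male_y_reference=None, background_median_interval=(lo, hi),
    )


class TestCallingCriteria:
    def _panel(self):
        from nipt_trio.panel import generate_panel_layout

        return generate_panel_layout({"1": 30_000_000}, 60, 100)

    def test_qualifying_duplication_called(self):
        panel = self._panel()  # 60 regions, 0.5 Mb spacing
        seg = Segment(0, 25, mean_z=2.5, median_z=2.6, chrom="1")
        calls = call_cnvs([seg], _db_with_interval(), panel, min_span=10_000_000)
        assert len(calls) == 1
        assert calls[0].direction == "dup"
        assert calls[0].n_regions == 25

    def test_too_few_regions_not_called(self):
        panel = self._panel()
        seg = Segment(0, 19, mean_z=3.0, median_z=3.0, chrom="1")
        assert call_cnvs([seg], _db_with_interval(), panel, min_span=1_000_000) == []

    def test_small_mean_z_not_called(self):
        panel = self._panel()
        seg = Segment(0, 30, mean_z=0.5, median_z=0.4, chrom="1")
        assert call_cnvs([seg], _db_with_interval(), panel) == []

    def test_median_inside_background_interval_not_called(self):
        panel = self._panel()
        seg = Segment(0, 30, mean_z=2.5, median_z=2.6, chrom="1")
        assert call_cnvs([seg], _db_with_interval(-3, 3), panel) == []

    def test_negative_median_called_as_deletion(self):
        panel = self._panel()
        seg = Segment(0, 30, mean_z=-2.5, median_z=-2.6, chrom="1")
        calls = call_cnvs([seg], _db_with_interval(), panel)
        assert calls and calls[0].direction == "del"


class TestEndToEnd:
    def test_fetal_duplication_called_with_accurate_boundaries(
        self, small_panel, small_baseline
    ):
        from nipt_trio.baseline import build_baseline
        from nipt_trio.simulate import simulate_reference_cohort

        cohort = simulate_reference_cohort(small_panel, 40, 1_000_000, 0.002, seed=77)
        db = build_baseline(cohort, small_panel, median_interval="segment")
        truth = SampleTruth(0.17, "XX", cnvs=[("1", 10_000_000, 40_000_000, +1)])
        s = simulate_region_counts(small_panel, truth, 1_000_000, 0.002, seed=5)
        calls = call_sample_cnvs(s, db, small_panel, min_span=10_000_000)
        dups = [c for c in calls if c.chrom == "1" and c.direction == "dup"]
        assert len(dups) == 1
        spacing = small_panel.chrom_spacing("1")
        assert abs(dups[0].start - 10_000_000) <= 1.5 * spacing
        assert abs(dups[0].end - 40_000_000) <= 1.5 * spacing
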