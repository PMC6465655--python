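import numpy as np
import pytest

from nipt_trio.simulate import (
    SampleTruth,
    SimulationError,
    draw_mixture_genotypes,
    read_counts_tsv,
    region_doses,
    simulate_pileups,
    simulate_reference_cohort,
    simulate_region_counts,
    write_counts_tsv,
)


class TestSampleTruth:
    def test_rejects_non_mendelian_genotypes(self):
        with pytest.raises(SimulationError, match="non-Mendelian"):
            SampleTruth(0.2, maternal_genotypes={"L": "AA"}, fetal_genotypes={"L": "BB"})

    def test_rejects_out_of_range_fraction(self):
        with pytest.raises(SimulationError):
            SampleTruth(1.5)

    @pytest.mark.parametrize(
        "sex,aneu,karyotype",
        [
            ("XX", [], "XX"),
            ("XY", [], "XY"),
            ("XX", [("X", "monosomy")], "X0"),
            ("XY", [("X", "XXY")], "XXY"),
        ],
    )
    def test_sex_karyotype(self, sex, aneu, karyotype):
        assert SampleTruth(0.2, sex, aneuploidies=aneu).sex_karyotype == karyotype


class TestDoseModel:
    def test_euploid_female_doses(self, small_panel):
        truth = SampleTruth(0.2, "XX")
        dose = region_doses(small_panel, truth)
        chroms = small_panel.backbone_chroms
        assert np.allclose(dose[chroms != "Y"], 1.0)
        assert np.allclose(dose[chroms == "Y"], 0.0)

    def test_trisomy_dose_is_one_plus_half_f(self, small_panel):
        truth = SampleTruth(0.2, "XX", aneuploidies=[("1", "trisomy")])
        dose = region_doses(small_panel, truth)
        chroms = small_panel.backbone_chroms
        assert np.allclose(dose[chroms == "1"], 1.10)
        assert np.allclose(dose[chroms == "2"], 1.0)

    def test_male_fetus_sex_chromosome_doses(self, small_panel):
        dose = region_doses(small_panel, SampleTruth(0.2, "XY"))
        chroms = small_panel.backbone_chroms
        assert np.allclose(dose[chroms == "X"], 0.90)  # 1 - f/2
        assert np.allclose(dose[chroms == "Y"], 0.10)  # f/2

    def test_xxy_keeps_female_x_dose_with_male_y_dose(self, small_panel):
        dose = region_doses(small_panel, SampleTruth(0.2, "XY", aneuploidies=[("X", "XXY")]))
        chroms = small_panel.backbone_chroms
        assert np.allclose(dose[chroms == "X"], 1.0)
        assert np.allclose(dose[chroms == "Y"], 0.10)

    def test_duplication_dose_ratio_monte_carlo(self, small_panel):
        """Mean dup/diploid count ratio converges to 1 + f/2 (here 1.10)."""
        truth = SampleTruth(0.2, "XX", cnvs=[("1", 0, 30_000_000, +1)])
        chroms = small_panel.backbone_chroms
        starts = small_panel.backbone_starts
        dup = (chroms == "1") & (starts < 30_000_000)
        dip = chroms == "2"
        tot_dup = tot_dip = 0.0
        for i in range(300):
            s = simulate_region_counts(small_panel, truth, 200_000, 0.0, seed=1000 + i)
            tot_dup += s.counts[dup].mean()
            tot_dip += s.counts[dip].mean()
        assert tot_dup / tot_dip == pytest.approx(1.10, rel=0.01)

    def test_cnv_on_missing_chromosome_errors(self, small_panel):
        truth = SampleTruth(0.2, cnvs=[("7", 0, 1_000_000, 1)])
        with pytest.raises(SimulationError, match="absent from panel"):
            simulate_region_counts(small_panel, truth, 1000)


class TestCountSampling:
    def test_counts_sum_to_total(self, small_panel):
        s = simulate_region_counts(small_panel, SampleTruth(0.2), 123_457, 0.002, seed=3)
        assert int(s.counts.sum()) == 123_457 == s.total_reads

    def test_deterministic_for_fixed_seed(self, small_panel):
        a = simulate_region_counts(small_panel, SampleTruth(0.2), 100_000, 0.002, seed=9)
        b = simulate_region_counts(small_panel, SampleTruth(0.2), 100_000, 0.002, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_overdispersion_increases_variance(self, small_panel):
        """Dirichlet-multinomial variance exceeds multinomial variance."""
        truth = SampleTruth(0.2, "XX")
        var = {}
        for disp in (0.0, 0.5):
            rows = np.stack([
                simulate_region_counts(small_panel, truth, 50_000, disp, seed=i).counts
                for i in range(1000)
            ])
            var[disp] = rows[:, small_panel.autosomal_index].var(axis=0).mean()
        assert var[0.5] > var[0.0]

    def test_cohort_reproducible_and_distinct_seeds_differ(self, small_panel):
        a = simulate_reference_cohort(small_panel, 4, 50_000, seed=5)
        b = simulate_reference_cohort(small_panel, 4, 50_000, seed=5)
        c = simulate_reference_cohort(small_panel, 4, 50_000, seed=6)
        assert all(np.array_equal(x.counts, y.counts) for x, y in zip(a, b))
        assert any(not np.array_equal(x.counts, y.counts) for x, y in zip(a, c))

    def test_cohort_of_one_errors(self, small_panel):
        with pytest.raises(SimulationError, match=">= 2"):
            simulate_reference_cohort(small_panel, 1, 1000)


class TestPileups:
    @pytest.mark.parametrize(
        "m,f,expected",
        [("AB", "AB", 0.5), ("AA", "AB", 0.10), ("BB", "AB", 0.90)],
    )
    def test_expected_alt_fraction_monte_carlo(self, m, f, expected):
        truth = SampleTruth(
            0.2,
            maternal_genotypes={f"L{i}": m for i in range(400)},
            fetal_genotypes={f"L{i}": f for i in range(400)},
        )
        piles = simulate_pileups(truth, mean_depth=300, error_rate=0.0, seed=11)
        frac = sum(p.alt_count for p in piles) / sum(p.depth for p in piles)
        assert frac == pytest.approx(expected, abs=0.01)

    def test_mendelian_violation_rejected_at_truth_level(self):
        with pytest.raises(SimulationError):
            SampleTruth(0.2, maternal_genotypes={"L": "BB"}, fetal_genotypes={"L": "AA"})

    def test_mixture_genotypes_respect_transmission(self):
        from nipt_trio.ptg import mendelian_compatible

        bafs = {f"S{i}": 0.4 for i in range(500)}
        m, f = draw_mixture_genotypes(bafs, seed=3)
        assert all(mendelian_compatible(m[k], f[k]) for k in bafs)


class TestCountsTSV:
    def test_roundtrip(self, small_panel, tmp_path):
        cohort = simulate_reference_cohort(small_panel, 3, 20_000, seed=1)
        path = tmp_path / "counts.tsv"
        write_counts_tsv(cohort, small_panel, path)
        again = read_counts_tsv(path, small_panel)
        assert [s.sample_id for s in again] == [s.sample_id for s in cohort]
        assert all(np.array_equal(a.counts, b.counts) for a, b in zip(again, cohort))
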