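import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nipt_trio import ptg
from nipt_trio.ptg import (
    AllelePileup,
    LocusInfo,
    PTGError,
    call_variants,
    disease_status,
    estimate_fetal_fraction_em,
    expected_alt_fraction,
    hwe_combo_priors,
    informative_combinations,
    locus_log_likelihood,
    map_genotypes,
    pgc_string,
    pseudo_tetraploid_space,
)
from nipt_trio.simulate import SampleTruth, simulate_pileups


class TestCombinationSpace:
    def test_exactly_seven_admissible_combinations(self):
        space = pseudo_tetraploid_space()
        assert space == ["AAAA", "AAAB", "ABAA", "ABAB", "ABBB", "BBAB", "BBBB"]
        assert len(space) == 9 - 2

    def test_non_mendelian_pairs_excluded(self):
        space = pseudo_tetraploid_space()
        assert "AABB" not in space
        assert "BBAA" not in space

    def test_exactly_four_informative_combinations(self):
        info = informative_combinations()
        assert info == ["AAAB", "ABAA", "ABBB", "BBAB"]
        assert set(info) <= set(pseudo_tetraploid_space())
        assert "ABAB" not in info


class TestExpectedAltFraction:
    @pytest.mark.parametrize(
        "combo,f,expected",
        [
            ("AAAB", 0.2, 0.10),
            ("ABAB", 0.2, 0.50),
            ("ABAB", 0.37, 0.50),
            ("BBAB", 0.2, 0.90),
            ("ABAA", 0.2, 0.40),
            ("ABBB", 0.2, 0.60),
        ],
    )
    def test_mixture_fractions(self, combo, f, expected):
        assert expected_alt_fraction(combo, f) == pytest.approx(expected)

    def test_inadmissible_combo_rejected(self):
        with pytest.raises(PTGError, match="inadmissible"):
            expected_alt_fraction("AABB", 0.2)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        combo=st.sampled_from(ptg.COMBOS),
        f=st.floats(0.001, 0.999),
    )
    def test_fraction_bounds_and_limits(self, combo, f):
        p = expected_alt_fraction(combo, f)
        assert 0.0 <= p <= 1.0
        # maternal-only limit as f -> 0
        maternal = {"AA": 0.0, "AB": 0.5, "BB": 1.0}[combo[:2]]
        assert expected_alt_fraction(combo, 1e-9) == pytest.approx(maternal, abs=1e-8)


class TestLikelihood:
    def test_balanced_heterozygote_pmf_value(self):
        # depth 10, alt 5, p = 0.5: ln(C(10,5) / 2^10) = -1.4021
        ll = locus_log_likelihood(AllelePileup("L", 5, 5), "ABAB", 0.2, error_rate=0.0)
        assert ll == pytest.approx(math.log(252 / 1024), abs=1e-4)
        assert ll == pytest.approx(-1.4021, abs=1e-4)

    def test_reference_homozygote_beats_alternate_on_ref_reads(self):
        pile = AllelePileup("L", 50, 0)
        ll_aaaa = locus_log_likelihood(pile, "AAAA", 0.2, error_rate=0.005)
        ll_bbbb = locus_log_likelihood(pile, "BBBB", 0.2, error_rate=0.005)
        assert ll_aaaa > ll_bbbb

    def test_zero_depth_uninformative(self):
        pile = AllelePileup("L", 0, 0)
        assert all(
            locus_log_likelihood(pile, c, 0.2) == 0.0 for c in ptg.COMBOS
        )

    def test_clamp_collision_gives_identical_likelihood(self):
        # at f=0.2 with a huge error floor both AAAA and AAAB clamp to 0.4
        pile = AllelePileup("L", 6, 4)
        ll1 = locus_log_likelihood(pile, "AAAA", 0.2, error_rate=0.4)
        ll2 = locus_log_likelihood(pile, "AAAB", 0.2, error_rate=0.4)
        assert ll1 == ll2


class TestPriors:
    def test_hwe_priors_sum_to_one_and_favor_reference(self):
        pri = hwe_combo_priors(0.01)
        assert pri.sum() == pytest.approx(1.0)
        assert pri[0] > 0.9  # AAAA dominates at rare alt allele


class TestEM:
    def _pileups(self, f=0.18, n=500, depth=200, seed=3):
        bafs = {f"S{i}": 0.3 for i in range(n)}
        from nipt_trio.simulate import draw_mixture_genotypes

        m, fet = draw_mixture_genotypes(bafs, seed)
        truth = SampleTruth(f, maternal_genotypes=m, fetal_genotypes=fet)
        return simulate_pileups(truth, depth, 0.005, seed + 1)

    def test_fetal_fraction_recovery(self):
        piles = self._pileups()
        priors = hwe_combo_priors(0.3)
        est = estimate_fetal_fraction_em(piles, priors, error_rate=0.005)
        assert est.converged
        assert abs(est.f - 0.18) <= 0.02

    def test_loglik_monotone_nondecreasing(self):
        piles = self._pileups(seed=9)
        est = estimate_fetal_fraction_em(piles, hwe_combo_priors(0.3))
        diffs = np.diff(est.loglik_trajectory)
        assert np.all(diffs >= -1e-6)

    def test_convergence_tolerance_honoured(self):
        piles = self._pileups(seed=5)
        est = estimate_fetal_fraction_em(piles, hwe_combo_priors(0.3), tolerance=0.001)
        assert est.converged
        assert abs(est.trajectory[-1] - est.trajectory[-2]) < 0.001

    def test_uninformative_loci_flagged(self):
        # perfectly balanced and perfectly homozygous loci carry no
        # fetal-fraction information
        piles = [
            AllelePileup("hom", 200, 0),
            AllelePileup("het", 100, 100),
            AllelePileup("alt", 0, 200),
        ]
        with pytest.warns(UserWarning, match="no informative loci"):
            est = estimate_fetal_fraction_em(piles, error_rate=0.0)
        assert not est.converged

    def test_requires_pileups(self):
        with pytest.raises(PTGError):
            estimate_fetal_fraction_em([])


class TestMAPGenotyping:
    def test_balanced_pileup_maps_to_double_heterozygote(self):
        calls = map_genotypes([AllelePileup("L", 99, 101)], f=0.20)
        assert calls[0].map_combo == "ABAB"

    def test_pure_reference_maps_to_aaaa(self):
        calls = map_genotypes([AllelePileup("L", 200, 0)], f=0.20)
        assert calls[0].map_combo == "AAAA"
        assert calls[0].fetal_call == "AA"

    def test_low_fraction_alt_maps_to_paternal_allele(self):
        # alt fraction 0.105 is closest to the AAAB expectation (f/2 = 0.10)
        calls = map_genotypes([AllelePileup("L", 179, 21)], f=0.20)
        assert calls[0].map_combo == "AAAB"

    def test_posterior_sums_to_one(self):
        calls = map_genotypes([AllelePileup("L", 120, 80)], f=0.20)
        assert sum(calls[0].posterior.values()) == pytest.approx(1.0, abs=1e-9)

    def test_tie_breaks_to_canonical_order(self):
        # zero depth: posterior equals the (uniform) prior; first combo wins
        calls = map_genotypes([AllelePileup("L", 0, 0)], f=0.20)
        assert calls[0].map_combo == "AAAA"


LOCI = {
    "GJB2:c.235delC": LocusInfo("GJB2:c.235delC", "GJB2", "hearing-loss"),
    "GJB2:c.299_300del": LocusInfo("GJB2:c.299_300del", "GJB2", "hearing-loss"),
    "PAH:c.G728A": LocusInfo("PAH:c.G728A", "PAH", "phenylketonuria"),
}


def _call(locus, combo):
    from nipt_trio.ptg import LocusGenotypeCall

    return LocusGenotypeCall(locus, {}, combo, combo[2:])


class TestVariantCalling:
    def test_carrier_allele_detected(self):
        variants = call_variants([_call("GJB2:c.235delC", "ABAB")], LOCI)
        assert variants[0].status == "heterozygous"
        assert variants[0].pgc == "ABab"

    def test_reference_fetus_reports_nd(self):
        variants = call_variants([_call("PAH:c.G728A", "ABAA")], LOCI)
        assert variants[0].status == "ND"
        assert variants[0].pgc == "ABaa"

    def test_compound_heterozygote_is_affected(self):
        calls = [_call("GJB2:c.235delC", "ABAB"), _call("GJB2:c.299_300del", "AAAB")]
        variants = call_variants(calls, LOCI)
        status = disease_status(variants, LOCI)
        assert status["GJB2"] == "affected"

    def test_single_heterozygote_is_carrier(self):
        variants = call_variants([_call("GJB2:c.235delC", "ABAB")], LOCI)
        assert disease_status(variants, LOCI)["GJB2"] == "carrier"

    def test_unknown_locus_errors(self):
        with pytest.raises(PTGError, match="metadata"):
            call_variants([_call("HBB:c.A52T", "ABAB")], LOCI)

    def test_pgc_casing(self):
        assert pgc_string("ABAB") == "ABab"
        assert pgc_string("AAAB") == "AAab"


class TestSensitivityMonotonicity:
    def test_detection_rate_nondecreasing_in_fraction_and_depth(self):
        """Fetal carrier-allele detection improves with f and with depth."""
        rates = {}
        for f in (0.05, 0.10, 0.20):
            for depth in (50, 150, 400):
                n = 300
                truth = SampleTruth(
                    f,
                    maternal_genotypes={f"L{i}": "AB" for i in range(n)},
                    fetal_genotypes={f"L{i}": "AB" for i in range(n)},
                )
                piles = simulate_pileups(truth, depth, 0.005, seed=17)
                calls = map_genotypes(piles, f, error_rate=0.005)
                rates[(f, depth)] = np.mean([c.fetal_call == "AB" for c in calls])
        for depth in (50, 150, 400):
            assert rates[(0.05, depth)] <= rates[(0.10, depth)] + 0.02
            assert rates[(0.10, depth)] <= rates[(0.20, depth)] + 0.02
        for f in (0.05, 0.10, 0.20):
            assert rates[(f, 50)] <= rates[(f, 150)] + 0.02
            assert rates[(f, 150)] <= rates[(f, 400)] + 0.02
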