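"""GSI cross simulation, segregation chi-square, allelism, marker roles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist

from srnase_screen.genetics import (MarkerSpec, ProgenyTable, SGenotype,
                                    attach_markers, classify_marker,
                                    classify_markers, expected_class3_count,
                                    gsi_cross, make_segregation_record,
                                    same_locus_test, segregation_test)
from srnase_screen.simulate import default_scenario, gen_cross_dataset


def ci99_halfwidth(n, p):
    return 2.576 * math.sqrt(p * (1 - p) / n)


# ---------------------------------------------------------------------------
# segregation_test: published chi-square table values
# ---------------------------------------------------------------------------

PUBLISHED = [
    # (present, absent, ratio, P printed to 4 s.f.)
    (58, 23, (1, 1), 1.007e-4),
    (58, 23, (3, 1), 0.4804),
    (71, 22, (1, 1), 3.75e-7),
    (71, 22, (3, 1), 0.7647),
    (43, 38, (3, 1), 5.25e-6),
    (38, 43, (3, 1), 5.29e-9),
    (39, 42, (1, 1), 0.7389),
    (38, 55, (1, 1), 0.07793),
    (51, 42, (3, 1), 7.118e-6),
    (81, 0, (3, 1), 2.04e-7),
]


class TestSegregationTest:
    @pytest.mark.parametrize("present,absent,ratio,expected", PUBLISHED)
    def test_published_values(self, present, absent, ratio, expected):
        _, df, p = segregation_test(present, absent, ratio)
        assert df == 1
        assert p == pytest.approx(expected, rel=5e-3)

    def test_perfect_fit(self):
        chi2, df, p = segregation_test(40, 40, (1, 1))
        assert chi2 == 0.0 and p == 1.0

    @pytest.mark.parametrize("k", [1, 10, 55])
    def test_p_one_at_equal_counts(self, k):
        assert segregation_test(k, k, (1, 1))[2] == 1.0

    def test_symmetric_in_counts_for_1to1(self):
        assert segregation_test(30, 50)[2] == pytest.approx(
            segregation_test(50, 30)[2])

    def test_matches_scipy_formula(self):
        chi2, _, p = segregation_test(51, 42, (3, 1))
        n = 93
        expect = np.array([n * 0.75, n * 0.25])
        obs = np.array([51, 42])
        stat = float((((obs - expect) ** 2) / expect).sum())
        assert chi2 == pytest.approx(stat)
        assert p == pytest.approx(float(chi2_dist.sf(stat, 1)))

    def test_rejects_negative_and_empty(self):
        with pytest.raises(ValueError):
            segregation_test(-1, 5)
        with pytest.raises(ValueError):
            segregation_test(0, 0)

    def test_type_one_error_close_to_alpha(self):
        """Under true 1:1 transmission P < 0.05 about 5% of the time."""
        rng = np.random.default_rng(2024)
        n, reps, alpha = 81, 10_000, 0.05
        present = rng.binomial(n, 0.5, size=reps)
        rejections = sum(segregation_test(int(k), n - int(k))[2] < alpha
                         for k in present)
        rate = rejections / reps
        # 3 sigma Monte-Carlo band around the asymptotic alpha
        assert abs(rate - alpha) < 3 * math.sqrt(alpha * (1 - alpha) / reps) + 0.01


class TestSegregationRecord:
    def test_fitted_ratio_labels(self):
        assert make_segregation_record("m", 81, 0).fitted_ratio == "1:0"
        assert make_segregation_record("m", 40, 40).fitted_ratio == "1:1"
        assert make_segregation_record("m", 58, 23).fitted_ratio == "3:1"
        assert make_segregation_record("m", 38, 55).fitted_ratio == "1:1"

    def test_counts_carried(self):
        r = make_segregation_record("m", 58, 23)
        assert (r.present, r.absent, r.n, r.all_present) == (58, 23, 81, False)


# ---------------------------------------------------------------------------
# gsi_cross
# ---------------------------------------------------------------------------

class TestGsiCross:
    def test_semi_compatible_cross_genotypes(self):
        mother = SGenotype(("S1", "Sx"))
        father = SGenotype(("S1", "Sy"))
        tab = gsi_cross(mother, father, 10_000, seed=7)
        counts = tab.genotype_counts()
        # only Sy pollen survives the S1Sx pistil
        assert set(counts) <= {"S1Sy", "SxSy"}
        n = tab.n
        for g in ("S1Sy", "SxSy"):
            assert abs(counts[g] / n - 0.5) < ci99_halfwidth(n, 0.5)

    def test_fully_incompatible_cross_raises(self):
        g = SGenotype(("S1", "S2"))
        with pytest.raises(ValueError, match="fully incompatible"):
            gsi_cross(g, SGenotype(("S1", "S2")), 10)

    def test_fully_compatible_cross_four_genotypes(self):
        tab = gsi_cross(SGenotype(("S1", "S2")), SGenotype(("S3", "S4")),
                        20_000, seed=3)
        counts = tab.genotype_counts()
        assert set(counts) == {"S1S3", "S1S4", "S2S3", "S2S4"}
        for c in counts.values():
            assert abs(c / tab.n - 0.25) < ci99_halfwidth(tab.n, 0.25)

    def test_self_fertile_allele_escapes_rejection(self):
        mother = SGenotype(("S1", "S2"))
        father = SGenotype(("S1", "Sf"))
        tab = gsi_cross(mother, father, 500, seed=1)
        assert set(tab.data["paternal_allele"]) == {"Sf"}

    def test_gsi_invariant_enforced_on_construction(self):
        mother = SGenotype(("S1", "Sx"))
        father = SGenotype(("S1", "Sy"))
        bad = pd.DataFrame({"maternal_allele": ["S1"],
                            "paternal_allele": ["S1"]})  # rejected pollen
        with pytest.raises(AssertionError):
            ProgenyTable(mother, father, bad)

    def test_n_validation(self):
        with pytest.raises(ValueError):
            gsi_cross(SGenotype(("S1", "S2")), SGenotype(("S3", "S4")), 0)

    def test_determinism(self):
        a = gsi_cross(SGenotype(("S1", "Sx")), SGenotype(("S1", "Sy")), 50,
                      seed=11)
        b = gsi_cross(SGenotype(("S1", "Sx")), SGenotype(("S1", "Sy")), 50,
                      seed=11)
        assert a.data.equals(b.data)


# ---------------------------------------------------------------------------
# attach_markers
# ---------------------------------------------------------------------------

class TestAttachMarkers:
    def cross(self, n=2000, seed=5):
        return gsi_cross(SGenotype(("S1", "Sx")), SGenotype(("S1", "Sy")), n,
                         seed=seed)

    def test_marker_linked_to_sole_compatible_pollen_always_present(self):
        tab = attach_markers(self.cross(), [MarkerSpec("m", "s_linked", "Sy")])
        present, absent = tab.marker_counts("m")
        assert absent == 0 and present == tab.n

    def test_marker_linked_to_maternal_allele_segregates_1to1(self):
        tab = attach_markers(self.cross(), [MarkerSpec("m", "s_linked", "Sx")])
        present, _ = tab.marker_counts("m")
        assert abs(present / tab.n - 0.5) < ci99_halfwidth(tab.n, 0.5)

    def test_unlinked_hemizygous_both_parents_3to1(self):
        spec = MarkerSpec("m", "unlinked", mother_copies=1, father_copies=1)
        tab = attach_markers(self.cross(), [spec])
        present, _ = tab.marker_counts("m")
        assert abs(present / tab.n - 0.75) < ci99_halfwidth(tab.n, 0.75)

    def test_homozygous_parent_marker_always_present(self):
        spec = MarkerSpec("m", "unlinked", mother_copies=2, father_copies=0)
        tab = attach_markers(self.cross(), [spec])
        assert tab.marker_counts("m") == (tab.n, 0)

    def test_full_recombination_halves_linkage(self):
        tab = attach_markers(self.cross(), [MarkerSpec("m", "s_linked", "Sy",
                                                       r=0.5)])
        present, _ = tab.marker_counts("m")
        assert abs(present / tab.n - 0.5) < ci99_halfwidth(tab.n, 0.5)

    def test_marker_for_absent_allele_raises(self):
        with pytest.raises(ValueError, match="absent from both parents"):
            attach_markers(self.cross(100),
                           [MarkerSpec("m", "s_linked", "S9")])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            MarkerSpec("m", "telepathic")
        with pytest.raises(ValueError):
            MarkerSpec("m", "s_linked")  # missing allele
        with pytest.raises(ValueError):
            MarkerSpec("m", "s_linked", "S1", r=0.7)
        with pytest.raises(ValueError):
            MarkerSpec("m", "unlinked", mother_copies=3)


# ---------------------------------------------------------------------------
# same_locus_test
# ---------------------------------------------------------------------------

class TestSameLocus:
    def make_table(self, seed=9, n=300):
        tab = gsi_cross(SGenotype(("S1", "Sx")), SGenotype(("S1", "Sy")), n,
                        seed=seed)
        markers = [MarkerSpec("mS1", "s_linked", "S1"),
                   MarkerSpec("mSx", "s_linked", "Sx"),
                   MarkerSpec("unl", "unlinked", mother_copies=1,
                              father_copies=1)]
        return attach_markers(tab, markers, seed=seed)

    def test_allelic_pair_true(self):
        # S1 pollen is rejected, so mS1 tracks the maternal S1 haplotype
        # and is exactly complementary to mSx
        tab = self.make_table()
        assert same_locus_test("mS1", "mSx", tab)

    def test_independent_marker_false(self):
        tab = self.make_table()
        assert not same_locus_test("mS1", "unl", tab)

    def test_marker_vs_itself_false(self):
        tab = self.make_table()
        assert not same_locus_test("mS1", "mS1", tab)

    def test_miscall_tolerance(self):
        tab = self.make_table()
        flipped = tab.data.copy()
        flipped.loc[flipped.index[0], "mS1"] = ~flipped.iloc[0]["mS1"]
        noisy = ProgenyTable(tab.mother, tab.father, flipped)
        assert not same_locus_test("mS1", "mSx", noisy)
        assert same_locus_test("mS1", "mSx", noisy, max_miscalls=1)


# ---------------------------------------------------------------------------
# classify_marker / classify_markers
# ---------------------------------------------------------------------------

class TestClassifyMarker:
    def test_homozygous_non_s_pattern(self):
        # present in every progeny of both directions
        role = classify_marker("hz", True, True,
                               make_segregation_record("hz", 81, 0),
                               make_segregation_record("hz", 93, 0))
        assert role == "homozygous_non_S"

    def test_unique_s_father_pattern(self):
        # all present when the father donates pollen, 1:1 reciprocally,
        # carried by the father only
        role = classify_marker("u", False, True,
                               make_segregation_record("u", 81, 0),
                               make_segregation_record("u", 51, 42))
        assert role == "unique_S_father"

    def test_unique_s_mother_pattern(self):
        role = classify_marker("u", True, False,
                               make_segregation_record("u", 39, 42),
                               make_segregation_record("u", 93, 0))
        assert role == "unique_S_mother"

    def test_unlinked_het_both_pattern(self):
        # 3:1 fits in both directions, carried by both parents
        role = classify_marker("m", True, True,
                               make_segregation_record("m", 58, 23),
                               make_segregation_record("m", 71, 22))
        assert role == "unlinked_het_both"

    def test_shared_s_requires_allelic_partner(self):
        fwd = make_segregation_record("s", 39, 42)
        rec = make_segregation_record("s", 47, 48)
        with_partner = classify_marker("s", True, True, fwd, rec,
                                       allelic_partners={"u"},
                                       unique_s_markers={"u"})
        without = classify_marker("s", True, True, fwd, rec,
                                  allelic_partners=set(),
                                  unique_s_markers={"u"})
        assert with_partner == "shared_S"
        assert without == "inconclusive"

    def test_unlinked_het_one_pattern(self):
        role = classify_marker("m", False, True,
                               make_segregation_record("m", 41, 40),
                               make_segregation_record("m", 45, 50))
        assert role == "unlinked_het_one"

    def test_all_present_one_way_but_both_parents_inconclusive(self):
        role = classify_marker("m", True, True,
                               make_segregation_record("m", 81, 0),
                               make_segregation_record("m", 51, 42))
        assert role == "inconclusive"


def recover_roles(seed, miscall_rate=0.0, include_het_one=True):
    scenario = default_scenario(include_het_one=include_het_one)
    fwd, rec, truth = gen_cross_dataset(scenario, n_forward=81,
                                        n_reciprocal=95,
                                        miscall_rate=miscall_rate, seed=seed)
    seg_f = {m: make_segregation_record(m, *fwd.marker_counts(m))
             for m in fwd.marker_ids}
    seg_r = {m: make_segregation_record(m, *rec.marker_counts(m))
             for m in rec.marker_ids}
    roles = classify_markers(scenario.parent_presence(), seg_f, seg_r,
                             forward_progeny=fwd)
    return roles, truth


class TestClassifyMarkersPanel:
    def test_single_seed_exact_recovery(self):
        roles, truth = recover_roles(seed=0)
        assert roles == truth

    def test_role_recovery_rate_100_seeds(self):
        """All five planted roles recovered in >= 99/100 seeds."""
        good = sum(recover_roles(seed)[0] == recover_roles(seed)[1]
                   for seed in range(100))
        assert good >= 99

    def test_recovery_with_genotyping_noise(self):
        """Ratio-based roles survive 2% miscalls; roles gated on strict
        all-present or strict complementarity (homozygous, unique-S,
        shared-S) may degrade and are not asserted."""
        roles, truth = recover_roles(seed=1, miscall_rate=0.02)
        for mid, role in truth.items():
            if role in ("unlinked_het_both", "unlinked_het_one"):
                assert roles[mid] == role


class TestExpectedClass3Count:
    @pytest.mark.parametrize("ploidy,si,expected", [
        ("diploid", "SI", 2),
        ("diploid", "SC", 1),
        ("haploid", "SI", 1),
        ("dihaploid", "SC", 1),
    ])
    def test_counts(self, ploidy, si, expected):
        assert expected_class3_count(ploidy, si) == expected

    def test_validation(self):
        with pytest.raises(ValueError):
            expected_class3_count("triploid", "SI")
        with pytest.raises(ValueError):
            expected_class3_count("diploid", "??")
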