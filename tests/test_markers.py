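"""Marker candidate construction, primer placement, in-silico PCR, scoring."""

import numpy as np
import pytest
from scipy import optimize
from scipy.stats import binom

from sexlink import markers as mk
from sexlink import poolscreen, simdata
from sexlink.dna import random_sequence, revcomp
from sexlink.markers import (
    Amplicon,
    PredictionRecord,
    PrimerPair,
    assign_sex,
    build_candidate,
    design_overlap_primers,
    discrimination_rate,
    discrimination_rate_from_counts,
    in_silico_pcr,
    predict_band,
    primer_overlaps_indel,
    select_indel_candidates,
    validate_marker,
)
from sexlink.poolscreen import InfoMetrics, PoolCounts, PoolSite
from tests.conftest import small_config


def make_indel_site(chrom="s1", pos=600, ref="A", alt="ATTGC",
                    female=(45, 0, 45), male=(20, 21, 41)):
    return PoolSite(chrom=chrom, pos=pos, ref=ref, alt=alt, vtype="InDel",
                    male=PoolCounts(*male), female=PoolCounts(*female),
                    metrics=InfoMetrics())


class TestSelectIndelCandidates:
    def test_snp_only_input_gives_empty(self):
        result = poolscreen.ScreenResult()
        result.passed = [PoolSite("s", 1, "A", "T", "SNP",
                                  PoolCounts(20, 20, 40), PoolCounts(40, 0, 40))]
        assert select_indel_candidates(result) == []

    def test_ordering_by_length_difference(self):
        result = poolscreen.ScreenResult()
        small = make_indel_site(pos=100, alt="AT")
        big = make_indel_site(pos=200, alt="ATTTTTTTT")
        result.passed = [small, big]
        assert select_indel_candidates(result) == [big, small]

    def test_simulated_candidates_are_exactly_planted_indels(self, clean_sim,
                                                             clean_screen):
        got = {(s.chrom, s.pos) for s in select_indel_candidates(clean_screen)}
        planted = {s.key for s in clean_sim.truth.sex_linked_sites
                   if s.vtype == "InDel"}
        assert got <= planted  # read noise may drop a site, never add one
        assert len(got) >= 0.8 * len(planted)


class TestBuildCandidate:
    def setup_method(self):
        rng = np.random.default_rng(61)
        self.seq = random_sequence(2000, rng)

    def test_insertion_haplotypes_differ_by_indel_size(self):
        site = make_indel_site(pos=1000, ref=self.seq[999],
                               alt=self.seq[999] + "TTGC")
        cand = build_candidate(site, self.seq, window=500)
        assert len(cand.hap_gametolog) - len(cand.hap_hom) == 4
        assert cand.indel_interval[1] > cand.indel_interval[0]

    def test_deletion_round_trip_restores_reference(self):
        ref_allele = self.seq[999:1005]
        site = make_indel_site(pos=1000, ref=ref_allele, alt=self.seq[999])
        cand = build_candidate(site, self.seq, window=500)
        lo, hi = cand.indel_interval_gametolog
        rebuilt = (cand.hap_gametolog[:lo] + site.ref + cand.hap_gametolog[hi:])
        assert rebuilt == cand.hap_hom == cand.region

    def test_female_fixed_for_alt_flips_haplotypes(self):
        site = make_indel_site(pos=1000, ref=self.seq[999],
                               alt=self.seq[999] + "TTGC",
                               female=(0, 45, 45))
        cand = build_candidate(site, self.seq, window=500)
        assert not cand.gametolog_is_alt
        assert cand.hap_gametolog == cand.region  # sex-limited allele is ref

    def test_window_truncated_by_scaffold_end_raises(self):
        site = make_indel_site(pos=100, ref=self.seq[99],
                               alt=self.seq[99] + "TT")
        with pytest.raises(ValueError, match="truncated"):
            build_candidate(site, self.seq, window=500)


class TestPrimerOverlapsIndel:
    def _candidate(self):
        rng = np.random.default_rng(67)
        seq = random_sequence(2000, rng)
        site = make_indel_site(pos=1000, ref=seq[999], alt=seq[999] + "GTCAA")
        return build_candidate(site, seq, window=500)

    def test_primer_entirely_upstream_does_not_overlap(self):
        cand = self._candidate()
        lo, _ = cand.indel_interval_gametolog
        pair = PrimerPair("p", cand.hap_gametolog[lo - 60 : lo - 36],
                          revcomp(cand.hap_gametolog[820:844]))
        assert primer_overlaps_indel(pair, cand) == (False, False)

    def test_primer_ending_inside_indel_overlaps(self):
        cand = self._candidate()
        lo, hi = cand.indel_interval_gametolog
        pair = PrimerPair("p", cand.hap_gametolog[hi - 20 : hi + 4],
                          revcomp(cand.hap_gametolog[820:844]))
        fwd, rev = primer_overlaps_indel(pair, cand)
        assert fwd and not rev

    def test_unbindable_primer_reported_as_non_overlapping(self):
        cand = self._candidate()
        pair = PrimerPair("p", "A" * 24, "C" * 24)
        assert primer_overlaps_indel(pair, cand) == (False, False)

    def test_agreement_with_interval_arithmetic_on_random_placements(self):
        cand = self._candidate()
        lo, hi = cand.indel_interval_gametolog
        rng = np.random.default_rng(71)
        for _ in range(50):
            start = int(rng.integers(0, len(cand.hap_gametolog) - 24))
            pair = PrimerPair("p", cand.hap_gametolog[start : start + 24],
                              revcomp(cand.hap_gametolog[820:844]))
            binding = cand.hap_gametolog.find(pair.fwd)
            expected = binding >= 0 and binding < hi and lo < binding + 24
            assert primer_overlaps_indel(pair, cand)[0] == expected


class TestInSilicoPcr:
    def test_template_without_forward_primer_gives_nothing(self):
        rng = np.random.default_rng(73)
        template = random_sequence(1000, rng)
        pair = PrimerPair("p", "ACGT" * 6, "TGCA" * 6)
        assert in_silico_pcr(template, pair) == []

    def test_constructed_amplicon_length(self):
        rng = np.random.default_rng(79)
        fwd = random_sequence(20, rng)
        rev = random_sequence(20, rng)
        template = random_sequence(50, rng) + fwd + \
            random_sequence(315, rng) + revcomp(rev) + random_sequence(50, rng)
        (amp,) = in_silico_pcr(template, PrimerPair("p", fwd, rev))
        assert amp.length == 20 + 315 + 20 == 355

    def test_product_outside_window_filtered(self):
        rng = np.random.default_rng(83)
        fwd = random_sequence(20, rng)
        rev = random_sequence(20, rng)
        template = fwd + random_sequence(210, rng) + revcomp(rev)
        assert in_silico_pcr(template, PrimerPair("p", fwd, rev)) == []
        # 20 + 210 + 20 = 250 < 300; widening the window recovers it
        (amp,) = in_silico_pcr(template, PrimerPair("p", fwd, rev,
                                                    min_product=100))
        assert amp.length == 250

    def test_reverse_complement_template_gives_same_lengths(self):
        rng = np.random.default_rng(89)
        fwd = random_sequence(22, rng)
        rev = random_sequence(22, rng)
        template = random_sequence(40, rng) + fwd + \
            random_sequence(300, rng) + revcomp(rev) + random_sequence(40, rng)
        pair = PrimerPair("p", fwd, rev)
        flipped_pair = PrimerPair("p", rev, fwd)
        lengths = [a.length for a in in_silico_pcr(template, pair)]
        flipped = [a.length for a in in_silico_pcr(revcomp(template),
                                                   flipped_pair)]
        assert lengths == flipped == [344]

    def test_internal_mismatch_tolerated_but_3prime_mismatch_blocks(self):
        rng = np.random.default_rng(97)
        fwd = random_sequence(20, rng)
        rev = random_sequence(20, rng)
        spacer = random_sequence(310, rng)

        def mutate(primer, index):
            base = "A" if primer[index] != "A" else "C"
            return primer[:index] + base + primer[index + 1 :]

        template_mid = mutate(fwd, 5) + spacer + revcomp(rev)
        template_3p = mutate(fwd, 18) + spacer + revcomp(rev)
        pair = PrimerPair("p", fwd, rev)
        assert in_silico_pcr(template_mid, pair, max_mismatch=0) == []
        assert len(in_silico_pcr(template_mid, pair, max_mismatch=1)) == 1
        assert in_silico_pcr(template_3p, pair, max_mismatch=1) == []


class TestAssignSex:
    @pytest.mark.parametrize(
        "band,model,expected",
        [(True, "XX_XY", "male"), (False, "XX_XY", "female"),
         (True, "ZZ_ZW", "female"), (False, "ZZ_ZW", "male")],
    )
    def test_band_semantics(self, band, model, expected):
        assert assign_sex(band, model) == expected


def clopper_pearson_oracle(k, n, alpha=0.05):
    """Independent CI oracle: direct inversion of the binomial tails."""
    lo = 0.0 if k == 0 else optimize.brentq(
        lambda p: binom.sf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12)
    hi = 1.0 if k == n else optimize.brentq(
        lambda p: binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12)
    return lo, hi


class TestDiscriminationRate:
    def test_field_validation_tally(self):
        result = discrimination_rate_from_counts(195, 196)
        assert result.rate_percent == 99.49
        lo, hi = result.ci95
        assert 0 < lo < 195 / 196 < hi <= 1

    def test_perfect_score(self):
        result = discrimination_rate_from_counts(10, 10)
        assert result.rate_percent == 100.00
        assert result.ci95[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("k,n", [(3, 4), (195, 196), (0, 7), (10, 10)])
    def test_ci_matches_tail_inversion_oracle(self, k, n):
        result = discrimination_rate_from_counts(k, n)
        lo, hi = clopper_pearson_oracle(k, n)
        assert result.ci95[0] == pytest.approx(lo, abs=1e-6)
        assert result.ci95[1] == pytest.approx(hi, abs=1e-6)

    def test_amplification_failure_counts_against_rate(self):
        records = [
            PredictionRecord("m1", "male", True, "male"),
            PredictionRecord("m2", "male", False, "female", amplified=False),
        ]
        result = discrimination_rate(records)
        assert result.n_total == 2 and result.n_correct == 1

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            discrimination_rate([])
        with pytest.raises(ValueError):
            discrimination_rate_from_counts(1, 0)


@pytest.fixture(scope="module")
def marked_sim():
    cfg = small_config(seed=37, seq_error_rate=0.0,
                       frac_filter_fail_sites=0.0, tag_dropout_rate=0.0)
    return simdata.run_simulation(cfg, with_tags=False)


class TestEndToEndMarker:
    def test_overlap_marker_separates_sexes_perfectly(self, marked_sim):
        sim = marked_sim
        screen = poolscreen.run_screen(sim.vcf_records,
                                       poolscreen.ScreenConfig(model="XX_XY"))
        indels = select_indel_candidates(screen)
        assert indels
        reference = {r.id: r for r in sim.reference}
        cand = build_candidate(indels[0], reference[indels[0].chrom])
        pair = design_overlap_primers(cand, name="MarkerT")
        assert primer_overlaps_indel(pair, cand)[0]
        result = validate_marker(sim.individuals, pair, cand.chrom, "XX_XY")
        assert result.rate_percent == 100.00
        bands = {r.individual_id: r.band_present for r in result.records}
        for ind in sim.individuals:
            assert bands[ind.id] == (ind.phenotypic_sex == "male")

    def test_predict_band_requires_known_scaffold(self, marked_sim):
        ind = marked_sim.individuals[0]
        pair = PrimerPair("p", "ACGT" * 6, "TGCA" * 6)
        with pytest.raises(ValueError, match="no sequence"):
            predict_band(ind, pair, "nonexistent_scaffold")
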