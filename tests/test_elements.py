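import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retrometh.core import ElementInstance, GenomicInterval
from retrometh.elements import (FIVE_LTR, INTERNAL, SOLO_LTR, THREE_LTR,
                                IdentityMatch, L1Structure, LtrAnnotation,
                                Pwm, approximate_motif_search,
                                classify_iap_fragment, classify_l1,
                                consensus_dmc_profile,
                                element_relative_position,
                                fragment_composition,
                                genomic_position_of_offset, ltr_domain_of,
                                pwm_scan, reverse_complement, sample_elements)


def el(start, end, strand="+", sub="L1MdA", cls="LINE/L1", cs=1, ce=None):
    return ElementInstance("chr1", start, end, strand, sub, cls,
                           consensus_start=cs,
                           consensus_end=ce or (ce if ce else end - start))


class TestRelativePosition:
    def test_plus_strand_offset(self):
        # 1-based element [1001..6500] -> 0-based start 1000
        e = el(1000, 6500)
        off, cons = element_relative_position(1100, e)
        assert off == 100 and cons == 100

    def test_minus_strand_offset(self):
        e = el(1000, 2000, strand="-")
        off, _ = element_relative_position(1901, e)
        assert off == 100

    def test_outside_element_rejected(self):
        with pytest.raises(ValueError):
            element_relative_position(900, el(1000, 2000))

    def test_consensus_shift(self):
        e = el(1000, 2500, cs=5001, ce=6500)
        off, cons = element_relative_position(1100, e)
        assert off == 100 and cons == 5100

    def test_missing_consensus_reported_none(self):
        e = ElementInstance("chr1", 1000, 2000, "+", "L1MdA", "LINE/L1")
        off, cons = element_relative_position(1500, e)
        assert off == 500 and cons is None

    @given(st.integers(0, 10**6), st.integers(10, 5000),
           st.sampled_from(["+", "-"]), st.data())
    @settings(max_examples=60, deadline=None)
    def test_round_trip_both_strands(self, start, length, strand, data):
        e = el(start, start + length, strand=strand)
        pos = data.draw(st.integers(start + 1, start + length))
        off, _ = element_relative_position(pos, e)
        assert 1 <= off <= length
        assert genomic_position_of_offset(off, e) == pos


class TestL1:
    def test_catalog_rule(self):
        e = el(10000, 16800)
        catalog = [GenomicInterval("chr1", 10050, 16750)]
        assert classify_l1(e, catalog)
        assert not classify_l1(el(40000, 46800), catalog)

    def test_length_fallback(self):
        assert not classify_l1(el(0, 800))
        assert classify_l1(el(0, 6800))

    def test_non_l1_rejected(self):
        with pytest.raises(ValueError):
            classify_l1(el(0, 7000, sub="IAPE", cls="LTR/ERVK"))

    def test_domain_map_is_ordered_partition(self):
        st_ = L1Structure(n_monomers=2)
        spans = st_.domain_spans()
        prev_end = 0
        for name in ("monomer", "5UTR", "ORF1", "ORF2", "3UTR"):
            s, e = spans[name]
            assert s == prev_end + 1
            prev_end = e
        assert prev_end == st_.length

    @pytest.mark.parametrize("offset,domain", [
        (150, "monomer"),   # inside monomer array (2 x 200 bp)
        (350, "monomer"),
        (450, "5UTR"),      # 203 bp 5'UTR after the monomers
        (700, "ORF1"),
        (5000, "ORF2"),
    ])
    def test_domain_of_offset(self, offset, domain):
        assert L1Structure(n_monomers=2).domain_of(offset) == domain

    def test_offset_beyond_structure_rejected(self):
        with pytest.raises(ValueError):
            L1Structure().domain_of(10**6)


class TestIapFragments:
    def _ltr(self, start, end, strand="+"):
        return el(start, end, strand=strand, sub="IAPE", cls="LTR/ERVK")

    def _int(self, start, end, strand="+"):
        return el(start, end, strand=strand, sub="IAPE-int", cls="LTR/ERVK")

    def test_internal_by_name(self):
        assert classify_iap_fragment(self._int(0, 5000), []) == INTERNAL

    def test_five_ltr_upstream_of_internal(self):
        ltr = self._ltr(1000, 1350)
        internal = self._int(1360, 6000)
        assert classify_iap_fragment(ltr, [internal]) == FIVE_LTR

    def test_three_ltr_downstream_of_internal(self):
        ltr = self._ltr(6010, 6360)
        internal = self._int(1360, 6000)
        assert classify_iap_fragment(ltr, [internal]) == THREE_LTR

    def test_minus_strand_orientation(self):
        # on the minus strand the 5'LTR sits at the genomic right
        ltr = self._ltr(6010, 6360, strand="-")
        internal = self._int(1360, 6000, strand="-")
        assert classify_iap_fragment(ltr, [internal]) == FIVE_LTR

    def test_solo_when_isolated(self):
        ltr = self._ltr(1000, 1350)
        internal = self._int(11000, 16000)  # 10 kb away
        assert classify_iap_fragment(ltr, [internal]) == SOLO_LTR

    def test_ambiguous_resolves_to_five_ltr(self):
        ltr = self._ltr(5000, 5350)
        left = self._int(1000, 4990)
        right = self._int(5360, 9000)
        assert classify_iap_fragment(ltr, [left, right]) == FIVE_LTR

    def test_non_ltr_rejected(self):
        with pytest.raises(ValueError):
            classify_iap_fragment(el(0, 350), [])

    def test_partition_on_synthetic_catalog(self, genome):
        ltr_cls = [e for e in genome.repeats
                   if e.repeat_class.startswith("LTR")]
        kinds = [classify_iap_fragment(e, ltr_cls) for e in ltr_cls]
        assert all(k in (FIVE_LTR, THREE_LTR, SOLO_LTR, INTERNAL)
                   for k in kinds)
        n_prov = sum(1 for k in kinds if k == FIVE_LTR)
        assert n_prov == sum(1 for k in kinds if k == THREE_LTR)

    def test_fragment_composition_recovers_seeding(self, genome,
                                                   annotated_sites):
        catalog = [e for e in genome.repeats
                   if e.repeat_class.startswith("LTR")]
        hypo = annotated_sites[(annotated_sites["call"] == "hypo")
                               & (annotated_sites["group"] == "LTR")]
        per_dmc = []
        for _, row in hypo.iterrows():
            for e in catalog:
                if e.chrom == row["chrom"] and e.contains_pos(int(row["pos"])):
                    per_dmc.append(e)
                    break
        comp = fragment_composition(per_dmc, catalog)
        comp = comp.set_index("fragment_kind")
        # seeding is exclusive to 5'LTR U3/R CpGs
        assert comp.loc[FIVE_LTR, "proportion"] == pytest.approx(1.0)


class TestLtrDomains:
    def test_landmark_boundaries(self):
        #        U3 with TATA | R ending at AATAAA end | U5
        seq = ("A" * 50 + "ATTATAAGA" + "T" * 20 + "AATAAA" + "G" * 40)
        ann = LtrAnnotation.from_sequence(seq)
        assert ann.r_start == 60       # first base after the TATA box
        assert ann.r_end == 85         # end of AATAAA
        assert ltr_domain_of(30, ann) == "U3"
        assert ltr_domain_of(70, ann) == "R"
        assert ltr_domain_of(100, ann) == "U5"

    def test_offset_beyond_ltr_rejected(self):
        ann = LtrAnnotation(length=100, r_start=40, r_end=70)
        with pytest.raises(ValueError):
            ltr_domain_of(101, ann)

    def test_missing_landmarks_rejected(self):
        with pytest.raises(ValueError):
            LtrAnnotation.from_sequence("ACGT" * 50)


class TestConsensusProfile:
    def _instances(self):
        return [el(i * 10000, i * 10000 + 500, sub="SUB", ce=500)
                for i in range(4)]

    def _dmcs(self, positions_and_calls):
        return pd.DataFrame([{"chrom": "chr1", "pos": p, "call": c}
                             for p, c in positions_and_calls])

    def test_recurrent_position_is_hot_spot(self):
        inst = self._instances()
        dmcs = self._dmcs([(i * 10000 + 120, "hypo") for i in range(3)])
        prof = consensus_dmc_profile(dmcs, inst, "SUB", hot_spot_min=3)
        assert prof.hypo_counts[119] == 3
        assert prof.hot_spots == [120]
        assert prof.n_elements == 3

    def test_scattered_positions_no_hot_spot(self):
        inst = self._instances()
        dmcs = self._dmcs([(0 * 10000 + 50, "hypo"), (10000 + 80, "hypo"),
                           (20000 + 110, "hypo")])
        prof = consensus_dmc_profile(dmcs, inst, "SUB", hot_spot_min=3)
        assert prof.hot_spots == []

    def test_counts_conserved(self):
        inst = self._instances()
        calls = [(i * 10000 + 50 + 10 * i, "hypo") for i in range(4)]
        calls += [(10000 + 200, "hyper")]
        prof = consensus_dmc_profile(self._dmcs(calls), inst, "SUB")
        assert prof.hypo_counts.sum() + prof.hyper_counts.sum() + \
            prof.n_unmapped == 5

    def test_seeded_hot_spots_recovered_exactly(self, genome, dmc_table):
        truth = genome.cpg_table
        seeded = sorted(set(
            truth.loc[(truth["region_label"] == "L1MdA:monomer")
                      & truth["full_length"], "consensus_pos"].astype(int)))
        prof = consensus_dmc_profile(dmc_table, genome.repeats, "L1MdA",
                                     hot_spot_min=3)
        assert prof.hot_spots == seeded


class TestSampling:
    def test_same_seed_same_subset(self):
        pop = [el(i * 1000, i * 1000 + 100) for i in range(143)]
        s1 = sample_elements(pop, 50, seed=7)
        s2 = sample_elements(pop, 50, seed=7)
        assert s1 == s2 and len(s1) == 50
        assert len({(e.start, e.end) for e in s1}) == 50

    def test_n_equal_population_identity(self):
        pop = [el(i * 1000, i * 1000 + 100) for i in range(10)]
        assert sample_elements(pop, 10, seed=0) == pop

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            sample_elements([el(0, 100)], 0, seed=0)


class TestPwm:
    def test_self_match_scores_one(self):
        seq = "ACGTGACCTA"
        pwm = Pwm.from_sequences([seq[2:8]])
        hits = pwm_scan(seq, pwm, rel_threshold=1.0, both_strands=False)
        assert any(h.position == 3 and h.score == pytest.approx(1.0)
                   for h in hits)

    def test_all_n_sequence_no_hits(self):
        pwm = Pwm.from_sequences(["ACGT"])
        assert pwm_scan("N" * 50, pwm) == []

    def test_degenerate_uniform_pwm_all_or_none(self):
        pwm = Pwm("uniform", np.zeros((4, 5)))
        hits = pwm_scan("ACGTACGTACGT", pwm, rel_threshold=0.9,
                        both_strands=False)
        assert len(hits) == 12 - 5 + 1  # every window maximal

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 80))
        pwm = Pwm.from_sequences([seq[10:18], seq[30:38]])
        fwd = pwm_scan(seq, pwm, rel_threshold=0.85)
        rc = pwm_scan(reverse_complement(seq), pwm, rel_threshold=0.85)
        flip = {"+": "-", "-": "+"}
        mapped = sorted((len(seq) - (h.position + pwm.length - 1) + 1,
                         flip[h.strand], round(h.score, 9)) for h in rc)
        assert mapped == sorted((h.position, h.strand, round(h.score, 9))
                                for h in fwd)

    def test_relative_score_range(self):
        pwm = Pwm.from_sequences(["AAAA", "AAAT"])
        lo, hi = pwm.score_range
        assert lo < hi
        assert pwm.relative_score("AAAA") == pytest.approx(1.0)


class TestApproximateMotif:
    MOTIF = "GAGACTCGAGC"  # 11-mer

    def test_exact_substring(self):
        seq = "TTT" + self.MOTIF + "TTT"
        hits = approximate_motif_search(seq, self.MOTIF)
        assert IdentityMatch(4, "+", 1.0) in hits

    def test_one_mismatch_passes_90pct(self):
        variant = "GAGTCTCGAGC"  # 1 mismatch: 10/11 = 0.909
        hits = approximate_motif_search("AA" + variant + "AA", self.MOTIF,
                                        min_identity=0.90)
        assert any(h.position == 3 and
                   h.identity == pytest.approx(10 / 11) for h in hits)

    def test_two_mismatches_fail(self):
        variant = "GAGTCTCGAGA"  # 9/11 = 0.818
        hits = approximate_motif_search("AA" + variant + "AA", self.MOTIF,
                                        min_identity=0.90)
        assert not any(h.strand == "+" and h.position == 3 for h in hits)

    def test_reverse_strand_detection(self):
        seq = "TT" + reverse_complement(self.MOTIF) + "TT"
        hits = approximate_motif_search(seq, self.MOTIF)
        assert any(h.strand == "-" and h.identity == 1.0 for h in hits)

    def test_motif_present_in_synthetic_l1_consensus(self, genome):
        # the generator plants an AER-like motif in the L1 5'UTR
        hits = approximate_motif_search(
            genome.consensus["L1MdA"].sequence, self.MOTIF, 0.90)
        assert any(h.identity == 1.0 for h in hits)
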