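"""Candidate proposal, acceptance filters and deduplication."""

import random

import pytest

from conftest import rna_revcomp
from lepimir import discovery, mapping, preprocess, synthetic
from lepimir.discovery import (PrecursorCandidate, Verdict, arm_support,
                               cluster_stacks, dedup_overlapping,
                               filter_structure, five_prime_homogeneity,
                               propose_candidates, validate_candidates)
from lepimir.folding import fold
from lepimir.mapping import ReadMapping


def _mk_candidate(reads=None, mature_arm="five_prime"):
    """A clean designed hairpin candidate with configurable read support."""
    mature = "GCGGCCGUAGCUGACGUGCCGU"
    prec = mature + "GAAUAUCA" + rna_revcomp(mature)
    st = fold(prec)
    mature_span = (0, 22) if mature_arm == "five_prime" else (30, 52)
    partner = st.partner()
    partners = [partner[i] for i in range(*mature_span) if i in partner]
    star_span = (min(partners), max(partners) + 1)
    cand = PrecursorCandidate(locus=("chr", 100, 100 + len(prec), "+"),
                              sequence=prec, structure=st,
                              mature_span=mature_span, star_span=star_span,
                              anchor_len=22)
    cand.reads = reads or []
    return cand


def _read(start, length, count, rid="r", strand="+"):
    return ReadMapping(read_id=rid, contig="chr", start=start,
                       end=start + length, strand=strand, mismatches=0,
                       count=count)


class TestFilterStructure:
    def test_strong_hairpin_passes(self):
        v = filter_structure(_mk_candidate())
        assert v.passed, v.reason

    def test_weak_energy_fails_with_reason(self):
        v = filter_structure(_mk_candidate(), energy_max=-60.0)
        assert not v.passed and "energy" in v.reason

    def test_mature_bulge_fails(self):
        cand = _mk_candidate()
        v = filter_structure(cand, max_mature_defect=-1)
        # a perfect stem has defect 0; forcing the ceiling below that fails
        assert not v.passed and "mature_defect" in v.reason


class TestFivePrimeHomogeneity:
    def test_modal_ratio(self):
        reads = [_read(110, 22, 8, "a"), _read(111, 21, 2, "b")]
        v = five_prime_homogeneity(_mk_candidate(reads))
        assert v.value == pytest.approx(0.8)
        assert v.passed

    def test_identical_starts_give_one(self):
        reads = [_read(100, 22, 5, "a"), _read(100, 21, 7, "b")]
        v = five_prime_homogeneity(_mk_candidate(reads))
        assert v.value == 1.0

    def test_uniform_starts_fail(self):
        reads = [_read(100 + i, 20, 1, f"r{i}") for i in range(10)]
        v = five_prime_homogeneity(_mk_candidate(reads))
        assert v.value == pytest.approx(0.1)
        assert not v.passed

    def test_no_mature_reads_fails(self):
        v = five_prime_homogeneity(_mk_candidate([]))
        assert not v.passed and "no mature reads" in v.reason

    def test_sparse_support_fails_for_insufficient_evidence(self):
        v = five_prime_homogeneity(_mk_candidate([_read(100, 22, 2, "a")]))
        assert not v.passed and "insufficient" in v.reason


class TestArmSupport:
    def test_both_arms_with_consistent_star_pass(self):
        cand = _mk_candidate()
        star_start = 100 + cand.star_span[0]
        reads = [_read(100, 22, 20, "mature"), _read(star_start, 21, 2, "star")]
        cand.reads = reads
        assert arm_support(cand).passed

    def test_mature_only_fails_single_arm(self):
        cand = _mk_candidate([_read(100, 22, 20, "mature")])
        v = arm_support(cand)
        assert not v.passed and v.reason == "single_arm"

    def test_misplaced_opposite_arm_read_is_not_star_evidence(self):
        cand = _mk_candidate()
        # a fragment on the 3' arm far from the predicted star start
        reads = [_read(100, 22, 20, "mature"),
                 _read(100 + cand.star_span[0] + 12, 20, 3, "fragment")]
        cand.reads = reads
        assert not arm_support(cand).passed

    def test_zero_reads_fails(self):
        v = arm_support(_mk_candidate([]))
        assert not v.passed and v.reason == "no_reads"


class TestDedup:
    def _cand(self, contig, start, end, strand, count):
        c = _mk_candidate([_read(start, 22, count)])
        c.locus = (contig, start, end, strand)
        return c

    def test_highest_count_wins_identical_locus(self):
        a = self._cand("c", 100, 180, "+", 50)
        b = self._cand("c", 100, 180, "+", 10)
        kept = dedup_overlapping([a, b])
        assert kept == [a] and b.status == "duplicate"

    def test_non_overlapping_all_retained(self):
        cands = [self._cand("c", i * 200, i * 200 + 80, "+", 5)
                 for i in range(4)]
        assert len(dedup_overlapping(cands)) == 4

    def test_opposite_strands_do_not_clash(self):
        a = self._cand("c", 100, 180, "+", 50)
        b = self._cand("c", 100, 180, "-", 10)
        assert len(dedup_overlapping([a, b])) == 2

    def test_chain_resolution_is_overlap_free(self, rng):
        cands = []
        for i in range(60):
            s = rng.randrange(0, 2000)
            cands.append(self._cand("c", s, s + rng.randint(40, 90), "+",
                                    rng.randint(1, 100)))
        kept = dedup_overlapping(cands)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                same = a.locus[0] == b.locus[0] and a.locus[3] == b.locus[3]
                overlap = a.locus[1] < b.locus[2] and b.locus[1] < a.locus[2]
                assert not (same and overlap)


class TestClusterStacks:
    def test_disjoint_mappings_form_separate_stacks(self):
        ms = [_read(0, 22, 5, "a"), _read(500, 22, 3, "b")]
        assert len(cluster_stacks(ms)) == 2

    def test_jittered_mappings_join_anchor(self):
        ms = [_read(100, 22, 50, "a"), _read(101, 21, 3, "b"),
              _read(99, 23, 2, "c")]
        stacks = cluster_stacks(ms)
        assert len(stacks) == 1 and len(stacks[0]) == 3


class TestEndToEnd:
    def test_no_mappings_no_candidates(self):
        assert propose_candidates([], {"c": "ACGT" * 100}) == []

    def test_planted_mirnas_recovered(self, small_library):
        genome = small_library["genome"]
        reads = [s for _, s in small_library["reads"]]
        kept, _ = preprocess.preprocess(reads)
        index = mapping.build_index(genome, k=9)
        mappings, multi = mapping.map_reads(kept, index)
        accepted, all_cands = discovery.discover(mappings, genome,
                                                 high_multimap=multi)
        truth = small_library["truth"]
        mir = truth[truth["kind"] == "mirna"]

        def covers(c):
            contig, s, e, strand = c.locus
            return any(r["contig"] == contig and r["strand"] == strand and
                       r["start"] < e and s < r["end"]
                       for _, r in mir.iterrows())

        assert accepted, "no candidates survived the filters"
        assert all(covers(c) for c in accepted)  # precision 1.0
        assert len(accepted) >= 0.8 * len(mir)

    def test_rejected_candidates_carry_reasons(self, small_library):
        genome = small_library["genome"]
        kept, _ = preprocess.preprocess([s for _, s in small_library["reads"]])
        index = mapping.build_index(genome, k=9)
        mappings, multi = mapping.map_reads(kept, index)
        _, all_cands = discovery.discover(mappings, genome, high_multimap=multi)
        for c in all_cands:
            assert [v.name for v in c.verdicts] == list(discovery.FILTER_ORDER)
            if c.status == "rejected":
                assert c.failing_reasons

    def test_repeat_anchored_candidates_rejected(self, small_library):
        genome = small_library["genome"]
        kept, _ = preprocess.preprocess([s for _, s in small_library["reads"]])
        index = mapping.build_index(genome, k=9)
        mappings, multi = mapping.map_reads(kept, index)
        _, all_cands = discovery.discover(mappings, genome, high_multimap=multi)
        repeat_fails = [c for c in all_cands
                        if (v := c.verdict("repeat")) and not v.passed]
        assert repeat_fails, "contaminant repeats should anchor candidates"
        assert all(c.status == "rejected" for c in repeat_fails)
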