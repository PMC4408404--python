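"""Pairing counts, duplex hybridisation energy and ddG site scoring."""

import random

import pytest

from conftest import rna_revcomp
from lepimir import datasets
from lepimir._energy import (PAIR_CODE, STACK, bulge_penalty, ENC,
                             internal_penalty)
from lepimir.folding import encode
from lepimir.targets import (count_pairing, duplex_energy, scan_transcript,
                             seed_match, site_score)


def oracle_duplex(mirna: str, site: str, max_loop: int = 8) -> float:
    """Exhaustive enumeration over every antiparallel pair chain."""
    a = encode(mirna)
    b = encode(site)[::-1]
    pairable = [(i, j) for i in range(len(a)) for j in range(len(b))
                if PAIR_CODE[a[i], b[j]] >= 0]
    best = 0

    def extend(chain_end, energy):
        nonlocal best
        best = min(best, energy)
        i0, j0 = chain_end
        for i, j in pairable:
            l1, l2 = i - i0 - 1, j - j0 - 1
            if l1 < 0 or l2 < 0 or l1 > max_loop or l2 > max_loop:
                continue
            if l1 == 0 and l2 == 0:
                cost = int(STACK[PAIR_CODE[a[i0], b[j0]], PAIR_CODE[a[i], b[j]]])
            elif l1 == 0 or l2 == 0:
                cost = bulge_penalty(l1 + l2)
            else:
                cost = internal_penalty(l1 + l2)
            extend((i, j), energy + cost)

    for start in pairable:
        extend(start, 0)
    return best / 10.0


class TestCountPairing:
    def test_synthetic_mir2768_ci_site(self):
        """The bundled stand-in reproduces the 21-of-22 pairable bases of
        the miR-2768-3p <-> ci consensus site (wobble counted as pairing)."""
        paired, total = count_pairing(datasets.SYNTHETIC_MIR2768_3P,
                                      datasets.SYNTHETIC_CI_SITE)
        assert (paired, total) == (21, 22)
        no_gu, _ = count_pairing(datasets.SYNTHETIC_MIR2768_3P,
                                 datasets.SYNTHETIC_CI_SITE, allow_GU=False)
        assert no_gu == 20

    def test_perfect_reverse_complement(self, rng):
        seq = "".join(rng.choice("ACGU") for _ in range(20))
        assert count_pairing(seq, rna_revcomp(seq)) == (20, 20)

    def test_poly_a_cannot_pair(self):
        assert count_pairing("A" * 15, "A" * 15) == (0, 15)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            count_pairing("ACGU", "ACGUA")

    def test_strand_swap_symmetry(self, rng):
        # the pairing relation is symmetric, so swapping strands (and, for
        # pure Watson-Crick pairing, reverse-complementing both) is neutral;
        # G:U wobble is deliberately asymmetric under complementation
        for _ in range(30):
            a = "".join(rng.choice("ACGU") for _ in range(18))
            b = "".join(rng.choice("ACGU") for _ in range(18))
            assert count_pairing(a, b) == count_pairing(b, a)
            assert count_pairing(a, b, allow_GU=False) == count_pairing(
                rna_revcomp(b), rna_revcomp(a), allow_GU=False)


class TestDuplexEnergy:
    def test_zero_when_nothing_pairs(self):
        assert duplex_energy("AAAA" * 4, "AAAA" * 4) == 0.0

    def test_nonpositive_whenever_a_pair_forms(self, rng):
        for _ in range(30):
            a = "".join(rng.choice("ACGU") for _ in range(16))
            b = "".join(rng.choice("ACGU") for _ in range(16))
            assert duplex_energy(a, b) <= 0.0

    def test_central_mismatch_raises_energy(self):
        a = "GCGGCCGUAGCUGACGUGCCGU"
        perfect = rna_revcomp(a)
        mutated = list(perfect)
        mutated[11] = "A" if mutated[11] != "A" else "C"
        assert duplex_energy(a, perfect) < duplex_energy(a, "".join(mutated))

    def test_oracle_equivalence_short_duplexes(self, rng):
        for _ in range(150):
            n, m = rng.randint(3, 8), rng.randint(3, 8)
            a = "".join(rng.choice("ACGU") for _ in range(n))
            b = "".join(rng.choice("ACGU") for _ in range(m))
            assert duplex_energy(a, b) == pytest.approx(oracle_duplex(a, b))


class TestSiteScore:
    def test_accessible_site_has_zero_opening_cost(self):
        mirna = datasets.SYNTHETIC_MIR2768_3P
        site = datasets.SYNTHETIC_CI_SITE
        transcript = "A" * 70 + site + "A" * 70
        sc = site_score(mirna, transcript, (70, 70 + 22))
        assert sc.open_cost == 0.0
        assert sc.combined_score == pytest.approx(sc.duplex_energy)
        assert sc.seed_matched and sc.predicted

    def test_buried_site_pays_opening_cost(self):
        mirna = datasets.SYNTHETIC_MIR2768_3P
        site = datasets.SYNTHETIC_CI_SITE
        # embed the site inside a designed hairpin so it is base-paired
        transcript = "A" * 30 + rna_revcomp(site) + "AAAA" + site + "A" * 30
        start = 30 + 22 + 4
        sc = site_score(mirna, transcript, (start, start + 22))
        assert sc.open_cost > 0.0
        assert sc.combined_score > sc.duplex_energy

    def test_combined_score_arithmetic_and_cutoff(self):
        mirna = datasets.SYNTHETIC_MIR2768_3P
        transcript = "A" * 70 + datasets.SYNTHETIC_CI_SITE + "A" * 70
        sc = site_score(mirna, transcript, (70, 92), cutoff=-20.0)
        assert sc.combined_score == pytest.approx(
            sc.duplex_energy + sc.open_cost)
        assert sc.predicted == (sc.combined_score <= -20.0)

    def test_span_outside_transcript_rejected(self):
        with pytest.raises(ValueError):
            site_score("ACGUACGUACGUACGUACGU", "ACGU" * 10, (30, 55))


class TestScan:
    def test_planted_site_is_top_hit(self):
        mirna = datasets.SYNTHETIC_MIR2768_3P
        transcript, span = datasets.synthetic_ci_transcript()
        hits = scan_transcript(mirna, transcript)
        assert hits, "no seed-matched windows found"
        assert hits[0].start == span[0] and hits[0].end == span[1]
        assert hits[0].predicted
        assert hits[0].paired_count == 21

    def test_scan_is_position_complete(self):
        mirna = datasets.SYNTHETIC_MIR2768_3P
        transcript, _ = datasets.synthetic_ci_transcript()
        hits = scan_transcript(mirna, transcript)
        L = len(mirna)
        seeded = [s for s in range(len(transcript) - L + 1)
                  if seed_match(mirna, transcript[s:s + L])]
        assert sorted(h.start for h in hits) == seeded
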