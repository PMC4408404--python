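"""Precursor candidate proposal and validation.

Read stacks (clusters of overlapping same-strand mappings anchored at the
most abundant read) nominate genomic windows; each window is excised in two
placements (stack as the 5' arm, stack as the 3' arm of an 80-nt window),
folded, and the better hairpin kept.  Candidates then pass through the
acceptance filters in a fixed order, each recording a verdict with a
reason:

1. ``repeat`` -- candidates anchored on reads mapping to more than 10 loci
   are rejected as repeat-derived;
2. ``structure`` -- stable hairpin: free energy below -18 kcal/mol, at
   least 18 base pairs on the main stem, no large (>4 nt) bulge or internal
   loop touching the mature region, exactly one terminal loop;
3. ``five_prime_homogeneity`` -- the modal mature 5' end must carry at
   least 80% of mature-arm reads (heterogeneous 5' ends mark degradation
   products of longer transcripts, not miRNAs);
4. ``arm_support`` -- reads must map to both arms of the hairpin (the
   star strand is direct evidence of processing from a duplex).

Finally overlapping predictions of the same locus are deduplicated,
keeping the most-supported candidate per strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .folding import HairpinStructure, fold, hairpin_metrics
from .mapping import ReadMapping, revcomp

WINDOW = 80
ENERGY_MAX = -18.0
MIN_STEM_PAIRS = 18
MAX_MATURE_DEFECT = 4
MIN_HOMOGENEITY = 0.8
MIN_MATURE_READS = 5  # weighted mature-arm reads needed to judge homogeneity
STACK_MIN_OVERLAP = 0.5
WINDOW_PAD = 4  # unpaired leader kept outside the stack when excising

FILTER_ORDER = ("repeat", "structure", "five_prime_homogeneity", "arm_support")


@dataclass
class Verdict:
    name: str
    passed: bool
    reason: str = ""
    value: Optional[float] = None


@dataclass
class PrecursorCandidate:
    locus: tuple                      # (contig, start, end, strand), 0-based
    sequence: str                     # RNA, 5'->3'
    structure: HairpinStructure
    mature_span: tuple                # within the candidate sequence
    star_span: Optional[tuple]
    reads: list = field(default_factory=list)       # mappings in the window
    anchor_read_id: str = ""
    anchor_len: int = 0               # length of the anchoring mature read
    verdicts: list = field(default_factory=list)
    status: str = "candidate"         # candidate | rejected | accepted | duplicate

    @property
    def total_count(self) -> int:
        return sum(m.count for m in self.reads)

    def verdict(self, name: str) -> Optional[Verdict]:
        for v in self.verdicts:
            if v.name == name:
                return v
        return None

    @property
    def failing_reasons(self) -> list[str]:
        return [v.reason for v in self.verdicts if not v.passed]


def cluster_stacks(mappings: list[ReadMapping]) -> list[list[ReadMapping]]:
    """Group same-strand mappings into read stacks.

    Stacks are seeded greedily at the highest-count unassigned mapping (the
    presumptive mature read); a mapping joins if it overlaps the anchor by
    at least half the shorter read.
    """
    stacks = []
    by_locus: dict[tuple, list[ReadMapping]] = {}
    for m in mappings:
        by_locus.setdefault((m.contig, m.strand), []).append(m)
    for (_contig, _strand), group in sorted(by_locus.items()):
        remaining = sorted(group, key=lambda m: (-m.count, m.start, m.read_id))
        while remaining:
            anchor = remaining[0]
            stack, rest = [], []
            for m in remaining:
                overlap = min(anchor.end, m.end) - max(anchor.start, m.start)
                if overlap >= STACK_MIN_OVERLAP * min(m.length, anchor.length):
                    stack.append(m)
                else:
                    rest.append(m)
            stacks.append(stack)
            remaining = rest
    return stacks


def _trim_to_stem(seq: str, structure, mature_span, pad: int = 2):
    """Bounds of the top-level helix whose span best covers the mature span.

    Returns ``(start, end)`` with ``pad`` unpaired nt kept on each side, or
    None when nothing pairs with the mature region.
    """
    pairs = structure.pairs
    top = [(i, j) for i, j in pairs
           if not any(a < i and j < b for a, b in pairs)]
    ms, me = mature_span
    best, best_ov = None, 0
    for i, j in top:
        ov = min(j + 1, me) - max(i, ms)
        if ov > best_ov:
            best, best_ov = (i, j), ov
    if best is None:
        return None
    i, j = best
    return max(0, i - pad), min(len(seq), j + 1 + pad)


def _excise(genome, contig, start, end, strand):
    seq = genome[contig][max(0, start):min(len(genome[contig]), end)]
    if strand == "-":
        seq = revcomp(seq)
    return seq.replace("T", "U")


def propose_candidates(mappings: list[ReadMapping], genome: dict[str, str],
                       window: int = WINDOW) -> list[PrecursorCandidate]:
    """Excise and fold a candidate precursor for every read stack.

    For each stack two windows are tried -- the stack at the 5' side and at
    the 3' side of the window -- and the placement with the lower folding
    energy is kept.  The stack span becomes the mature span; the star span
    is read off the structure as the paired partner of the mature arm.
    """
    candidates = []
    by_locus: dict[tuple, list[ReadMapping]] = {}
    for m in mappings:
        by_locus.setdefault((m.contig, m.strand), []).append(m)
    for stack in cluster_stacks(mappings):
        anchor = max(stack, key=lambda m: (m.count, -m.start))
        if anchor.length > window:
            continue  # stack too long for a precursor window
        contig_len = len(genome[anchor.contig])
        placements = []
        for mode in ("stack5p", "stack3p"):
            if (mode == "stack5p") == (anchor.strand == "+"):
                gstart = anchor.start - WINDOW_PAD
            else:
                gstart = anchor.end + WINDOW_PAD - window
            gstart = max(0, min(gstart, contig_len - window))
            gend = gstart + window
            seq = _excise(genome, anchor.contig, gstart, gend, anchor.strand)
            structure = fold(seq)
            placements.append((structure.energy_kcal_mol, mode, gstart, gend,
                               seq, structure))
        placements.sort(key=lambda p: p[0])
        _, _mode, gstart, gend, seq, structure = placements[0]
        if anchor.strand == "+":
            mstart = anchor.start - gstart
        else:
            mstart = gend - anchor.end
        mature_span = (mstart, mstart + anchor.length)
        # trim the window to the stem enclosing the mature span and refold:
        # flanking genomic sequence outside the precursor otherwise folds
        # into spurious secondary stems
        trimmed = _trim_to_stem(seq, structure, mature_span)
        if trimmed is not None:
            ts, te = trimmed
            seq = seq[ts:te]
            structure = fold(seq)
            mature_span = (max(0, mature_span[0] - ts),
                           min(te - ts, mature_span[1] - ts))
            if anchor.strand == "+":
                gstart, gend = gstart + ts, gstart + te
            else:
                gstart, gend = gend - te, gend - ts
        partner = structure.partner()
        partners = [partner[i] for i in range(*mature_span) if i in partner]
        star_span = (min(partners), max(partners) + 1) if partners else None
        # all same-strand reads inside the window (star-arm reads form
        # their own stack but still support this candidate)
        in_window = [m for m in by_locus[(anchor.contig, anchor.strand)]
                     if m.start >= gstart - 2 and m.end <= gend + 2]
        candidates.append(PrecursorCandidate(
            locus=(anchor.contig, gstart, gend, anchor.strand), sequence=seq,
            structure=structure, mature_span=mature_span, star_span=star_span,
            reads=in_window, anchor_read_id=anchor.read_id,
            anchor_len=anchor.length))
    return candidates


def filter_structure(candidate: PrecursorCandidate, energy_max: float = ENERGY_MAX,
                     min_stem_pairs: int = MIN_STEM_PAIRS,
                     max_mature_defect: int = MAX_MATURE_DEFECT) -> Verdict:
    """Stable-hairpin criteria: energy, stem pairing, mature-region defects."""
    m = hairpin_metrics(candidate.structure, candidate.mature_span)
    reasons = []
    if not candidate.structure.energy_kcal_mol < energy_max:
        reasons.append(f"energy {candidate.structure.energy_kcal_mol:.1f} "
                       f">= {energy_max}")
    if m["stem_pair_count"] < min_stem_pairs:
        reasons.append(f"stem pairs {m['stem_pair_count']} < {min_stem_pairs}")
    if m["max_defect_in_mature"] > max_mature_defect:
        reasons.append(f"mature_defect {m['max_defect_in_mature']} > "
                       f"{max_mature_defect}")
    if m["n_hairpin_loops"] != 1:
        reasons.append(f"hairpin loops {m['n_hairpin_loops']} != 1")
    mature_len = candidate.mature_span[1] - candidate.mature_span[0]
    if candidate.anchor_len and mature_len < candidate.anchor_len - 2:
        reasons.append("mature read extends outside the main stem")
    return Verdict("structure", not reasons, "; ".join(reasons),
                   value=candidate.structure.energy_kcal_mol)


def _arm_spans(candidate: PrecursorCandidate):
    """5' and 3' arm spans in window coordinates, split at the terminal loop."""
    pairs = candidate.structure.pairs
    if not pairs:
        mid = len(candidate.sequence) // 2
        return (0, mid), (mid, len(candidate.sequence))
    innermost = max(pairs, key=lambda p: p[0])
    loop_start, loop_end = innermost[0] + 1, innermost[1]
    return (0, loop_start), (loop_end, len(candidate.sequence))


def _window_position(candidate, m: ReadMapping):
    """Map a genomic mapping to candidate-window coordinates (5' start)."""
    contig, gstart, gend, strand = candidate.locus
    if strand == "+":
        return m.start - gstart
    return gend - m.end


def five_prime_homogeneity(candidate: PrecursorCandidate,
                           min_reads: int = MIN_MATURE_READS,
                           threshold: float = MIN_HOMOGENEITY) -> Verdict:
    """Share of mature-arm read counts at the modal 5' position.

    Weighted by collapsed-read counts; a handful of reads cannot establish
    homogeneity, so candidates with fewer than ``min_reads`` total
    mature-arm reads fail for insufficient evidence.
    """
    arm5, arm3 = _arm_spans(candidate)
    mature_arm = arm5 if candidate.mature_span[0] < arm5[1] else arm3
    counts: dict[int, int] = {}
    for m in candidate.reads:
        p5 = _window_position(candidate, m)
        if mature_arm[0] <= p5 < mature_arm[1]:
            counts[p5] = counts.get(p5, 0) + m.count
    total = sum(counts.values())
    if total == 0:
        return Verdict("five_prime_homogeneity", False, "no mature reads")
    if total < min_reads:
        return Verdict("five_prime_homogeneity", False,
                       f"insufficient mature read support ({total} < {min_reads})",
                       value=None)
    h = max(counts.values()) / total
    passed = h >= threshold
    return Verdict("five_prime_homogeneity", passed,
                   "" if passed else f"h={h:.2f} < {threshold}", value=h)


STAR_TOLERANCE = 7  # nt between a star read 5' end and the predicted star span


def arm_support(candidate: PrecursorCandidate) -> Verdict:
    """Reads must map to both arms of the hairpin.

    Mature-arm support is any read within the mature arm; opposite-arm
    support must additionally start near the structure-predicted star span
    (Dicer leaves the star strand at the position paired with the mature
    strand, so arbitrarily placed fragments on the other arm are
    degradation, not processing evidence).
    """
    if not candidate.reads:
        return Verdict("arm_support", False, "no_reads")
    arm5, arm3 = _arm_spans(candidate)
    mature_is_5p = candidate.mature_span[0] < arm5[1]
    mature_arm, star_arm = (arm5, arm3) if mature_is_5p else (arm3, arm5)
    star_start = candidate.star_span[0] if candidate.star_span else None
    w_mature = w_star = 0
    for m in candidate.reads:
        p5 = _window_position(candidate, m)
        if mature_arm[0] <= p5 < mature_arm[1]:
            w_mature += m.count
        elif star_arm[0] - 2 <= p5 < star_arm[1]:
            if star_start is not None and abs(p5 - star_start) <= STAR_TOLERANCE:
                w_star += m.count
    if w_mature and w_star:
        return Verdict("arm_support", True, value=min(w_mature, w_star))
    reason = "single_arm" if (w_mature or w_star) else "no_reads_in_arms"
    return Verdict("arm_support", False, reason, value=max(w_mature, w_star))


def validate_candidates(candidates: list[PrecursorCandidate],
                        high_multimap: set[str] = frozenset(),
                        energy_max: float = ENERGY_MAX,
                        min_stem_pairs: int = MIN_STEM_PAIRS,
                        max_mature_defect: int = MAX_MATURE_DEFECT,
                        min_homogeneity: float = MIN_HOMOGENEITY,
                        ) -> list[PrecursorCandidate]:
    """Apply all acceptance filters in order, recording every verdict."""
    for c in candidates:
        repeat_hit = c.anchor_read_id in high_multimap
        c.verdicts = [Verdict("repeat", not repeat_hit,
                              "repeat-derived" if repeat_hit else "")]
        c.verdicts.append(filter_structure(c, energy_max, min_stem_pairs,
                                           max_mature_defect))
        c.verdicts.append(five_prime_homogeneity(c, threshold=min_homogeneity))
        c.verdicts.append(arm_support(c))
        c.status = "accepted" if all(v.passed for v in c.verdicts) else "rejected"
    return candidates


def dedup_overlapping(candidates: list[PrecursorCandidate]
                      ) -> list[PrecursorCandidate]:
    """Remove duplicate predictions of the same locus.

    Among same-strand candidates with overlapping loci the one with the
    highest total read count wins (ties: lower start); losers are marked
    ``duplicate``.  The retained set is pairwise non-overlapping per strand.
    """
    order = sorted(candidates,
                   key=lambda c: (-c.total_count, c.locus[1], c.locus[0]))
    retained: list[PrecursorCandidate] = []
    for c in order:
        contig, start, end, strand = c.locus
        clash = any(r.locus[0] == contig and r.locus[3] == strand and
                    r.locus[1] < end and start < r.locus[2]
                    for r in retained)
        if clash:
            c.status = "duplicate"
        else:
            retained.append(c)
    return sorted(retained, key=lambda c: (c.locus[0], c.locus[1]))


def discover(mappings, genome, high_multimap: set[str] = frozenset(),
             window: int = WINDOW, **thresholds):
    """Propose, validate and deduplicate candidates; returns (accepted, all)."""
    candidates = propose_candidates(mappings, genome, window=window)
    validate_candidates(candidates, high_multimap, **thresholds)
    accepted = dedup_overlapping([c for c in candidates if c.status == "accepted"])
    return accepted, candidates


def write_gff3(candidates, path) -> None:
    """1-based GFF3 of retained precursor loci."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(candidates, 1):
            contig, start, end, strand = c.locus
            fh.write(f"{contig}\tlepimir\tmiRNA_primary_transcript\t"
                     f"{start + 1}\t{end}\t.\t{strand}\t.\t"
                     f"ID=cand_{i};reads={c.total_count}\n")


def write_candidate_fasta(candidates, path) -> None:
    """Accepted precursors with their mature and star subsequences."""
    with open(path, "w") as fh:
        for i, c in enumerate(candidates, 1):
            contig, start, end, strand = c.locus
            name = f"cand_{i}_{contig}_{start + 1}_{end}_{strand}"
            fh.write(f">{name} precursor\n{c.sequence}\n")
            ms, me = c.mature_span
            fh.write(f">{name}_mature\n{c.sequence[ms:me]}\n")
            if c.star_span:
                ss, se = c.star_span
                fh.write(f">{name}_star\n{c.sequence[ss:se]}\n")


def write_verdicts_tsv(candidates, path) -> None:
    with open(path, "w") as fh:
        cols = "\t".join(FILTER_ORDER)
        fh.write(f"contig\tstart\tend\tstrand\tstatus\ttotal_reads\t{cols}\treasons\n")
        for c in candidates:
            contig, start, end, strand = c.locus
            marks = "\t".join(
                ("pass" if v and v.passed else "FAIL") if (v := c.verdict(n))
                else "-" for n in FILTER_ORDER)
            fh.write(f"{contig}\t{start + 1}\t{end}\t{strand}\t{c.status}\t"
                     f"{c.total_count}\t{marks}\t"
                     f"{'; '.join(c.failing_reasons)}\n")
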