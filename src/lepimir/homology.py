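"""Homology annotation of validated precursors.

Candidates are classified as conserved (reciprocal-best local-alignment
match to a known-precursor reference set) or novel, and screened against
decoy sets (repeat, structural-RNA and bacterial stand-ins) to remove
rRNA-fragment-like contaminants.  Alignment scoring follows the BLASTn
parameterisation used for short, weakly conserved precursors: word size 4,
match +5, mismatch -4, affine gaps costing open 8 plus extend 6 per base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .mapping import revcomp


@dataclass(frozen=True)
class AlignmentScoring:
    word_size: int = 4
    match_reward: int = 5
    mismatch_penalty: int = -4
    gap_open: int = 8
    gap_extend: int = 6
    min_report_score: int = 50

    def gap_cost(self, length: int) -> int:
        return self.gap_open + self.gap_extend * length


@dataclass
class HomologyHit:
    query: str
    subject: str
    score: int
    identity: float
    query_span: tuple  # 0-based half-open on the query
    subject_span: tuple
    strand: str = "+"


def _has_seed(q: str, s: str, w: int) -> bool:
    if len(q) < w or len(s) < w:
        return False
    words = {q[i:i + w] for i in range(len(q) - w + 1)}
    return any(s[i:i + w] in words for i in range(len(s) - w + 1))


def _smith_waterman(q: str, s: str, sc: AlignmentScoring):
    """Affine-gap local alignment; returns (score, qspan, sspan, identity)."""
    n, m = len(q), len(s)
    NEG = -1 << 30
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s (deletion from q)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in q
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - sc.gap_cost(1), E[i - 1][j] - sc.gap_extend)
            F[i][j] = max(H[i][j - 1] - sc.gap_cost(1), F[i][j - 1] - sc.gap_extend)
            sub = sc.match_reward if q[i - 1] == s[j - 1] else sc.mismatch_penalty
            h = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best == 0:
        return 0, (0, 0), (0, 0), 0.0
    # traceback from the best cell
    i, j = bi, bj
    matches = aligned = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0:
                break
            sub = sc.match_reward if q[i - 1] == s[j - 1] else sc.mismatch_penalty
            if H[i][j] == H[i - 1][j - 1] + sub:
                matches += q[i - 1] == s[j - 1]
                aligned += 1
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            aligned += 1
            if E[i][j] == E[i - 1][j] - sc.gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:
            aligned += 1
            if F[i][j] == F[i][j - 1] - sc.gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
    identity = matches / aligned if aligned else 0.0
    return best, (i, bi), (j, bj), identity


def local_align(query: str, subject: str, scoring: AlignmentScoring = AlignmentScoring(),
                query_name: str = "query", subject_name: str = "subject",
                ) -> Optional[HomologyHit]:
    """Best seeded local alignment of query vs subject (both strands).

    Requires at least one exact ``word_size`` seed on a strand before that
    strand is aligned (BLAST-style); returns None when no alignment reaches
    ``min_report_score``.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    q = query.upper().replace("U", "T")
    best_hit = None
    for strand in ("+", "-"):
        s = subject.upper().replace("U", "T")
        if strand == "-":
            s = revcomp(s)
        if not _has_seed(q, s, scoring.word_size):
            continue
        score, qspan, sspan, ident = _smith_waterman(q, s, scoring)
        if score >= scoring.min_report_score and (
                best_hit is None or score > best_hit.score):
            if strand == "-":
                sspan = (len(s) - sspan[1], len(s) - sspan[0])
            best_hit = HomologyHit(query=query_name, subject=subject_name,
                                   score=score, identity=ident,
                                   query_span=qspan, subject_span=sspan,
                                   strand=strand)
    return best_hit


def _top_hit(seq_name, seq, against: dict, scoring):
    """Best subject for one query; ties for the top score are ambiguous."""
    best = None
    tie = False
    for name, other in against.items():
        hit = local_align(seq, other, scoring, query_name=seq_name,
                          subject_name=name)
        if hit is None:
            continue
        if best is None or hit.score > best.score:
            best, tie = hit, False
        elif hit.score == best.score and hit.subject != best.subject:
            tie = True
    return None if tie else best


def reciprocal_best(candidates: dict[str, str], reference: dict[str, str],
                    scoring: AlignmentScoring = AlignmentScoring()):
    """Reciprocal-best-hit verification against a reference precursor set.

    Returns ``(verified, novel)``: verified maps candidate name to reference
    name where each is the other's unambiguous top hit; everything else is
    passed on as novel.  The matching is partial: no candidate or reference
    appears in two verified pairs.
    """
    if not candidates or not reference:
        raise ValueError("empty candidate or reference set")
    cand_best = {name: _top_hit(name, seq, reference, scoring)
                 for name, seq in candidates.items()}
    ref_best = {name: _top_hit(name, seq, candidates, scoring)
                for name, seq in reference.items()}
    verified = {}
    for cname, hit in cand_best.items():
        if hit is None:
            continue
        back = ref_best.get(hit.subject)
        if back is not None and back.subject == cname:
            verified[cname] = hit.subject
    novel = [c for c in candidates if c not in verified]
    return verified, novel


def screen_contaminants(candidates: dict[str, str],
                        decoy_sets: dict[str, dict[str, str]],
                        scoring: AlignmentScoring = AlignmentScoring()):
    """Flag candidates hitting any decoy set (repeats / structural RNA / bacterial).

    Returns ``(flags, warnings)``: flags maps candidate name to the name of
    the first decoy set it hits at ``min_report_score``; empty or missing
    decoy sets are skipped with a recorded warning.
    """
    flags: dict[str, str] = {}
    warned: list[str] = []
    for set_name, decoys in decoy_sets.items():
        if not decoys:
            warned.append(f"decoy set {set_name!r} empty or missing; screen skipped")
            continue
        for cname, cseq in candidates.items():
            if cname in flags:
                continue
            for dseq in decoys.values():
                if local_align(cseq, dseq, scoring) is not None:
                    flags[cname] = set_name
                    break
    return flags, warned
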