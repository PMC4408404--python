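"""Accessibility-aware miRNA target-site scoring.

Scores a candidate miRNA:site interaction as the free energy gained by
forming the miRNA:target duplex plus the free energy lost opening local
target secondary structure to make the site accessible (a ddG score in the
PITA tradition).  Sites at or below the reporting cutoff (default -20
kcal/mol on the combined score) are called predicted targets.  Coding
sequence is scanned exactly like 3'-UTR sequence: lepidopteran miR-2768
targets *cubitus interruptus* inside the coding region, and nothing in the
energetics distinguishes the two.

Opening costs are computed as MFE differences (constrained minus
unconstrained fold of the flanked site context) rather than ensemble free
energies, consistent with the MFE-only folding engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._energy import ENC, PAIR_CODE, STACK, bulge_penalty, internal_penalty
from .folding import encode, fold

#: WC pair codes in the pair table (AU, UA, CG, GC); 4/5 are the G:U wobbles
_WC_CODES = {0, 1, 2, 3}
_GU_CODES = {4, 5}

MAX_DUPLEX_LOOP = 8


@dataclass
class TargetSiteScore:
    mirna: str
    transcript: str
    start: int                 # 0-based, on the transcript
    end: int
    duplex_energy: float       # kcal/mol, <= 0 when any pair forms
    open_cost: float           # kcal/mol, >= 0
    combined_score: float      # duplex + opening
    paired_count: int
    seed_matched: bool
    predicted: bool


def count_pairing(mirna: str, site: str, allow_GU: bool = True):
    """Count pairable positions in the ungapped antiparallel register.

    ``mirna[i]`` faces ``site[L-1-i]``; a position counts when the two bases
    form a Watson-Crick pair, or a G:U wobble when ``allow_GU``.  Returns
    ``(paired, total)``.
    """
    a = encode(mirna)
    b = encode(site)
    if len(a) != len(b):
        raise ValueError("count_pairing requires equal-length sequences")
    L = len(a)
    ok = _WC_CODES | _GU_CODES if allow_GU else _WC_CODES
    paired = sum(1 for i in range(L) if PAIR_CODE[a[i], b[L - 1 - i]] in ok)
    return paired, L


def duplex_energy(mirna: str, site: str) -> float:
    """Optimal antiparallel hybridisation energy (kcal/mol).

    A two-strand dynamic program over pair positions with nearest-neighbor
    stacking and affine bulge/internal-loop penalties between consecutive
    pairs (loop sides capped at ``MAX_DUPLEX_LOOP`` nt).  Initiation is
    taken as zero, so the energy is <= 0 whenever at least one pair forms,
    and exactly 0.0 when nothing can pair.
    """
    a = encode(mirna)
    b = encode(site)[::-1]  # antiparallel: a[i] faces reversed-site[j]
    n, m = len(a), len(b)
    NEG = None
    # D[i][j]: best energy of a duplex whose last pair is (a[i], b[j])
    D = np.full((n, m), 1 << 20, dtype=np.int64)
    best = 0
    for i in range(n):
        for j in range(m):
            if PAIR_CODE[a[i], b[j]] < 0:
                continue
            e = 0  # duplex starting at this pair
            for l1 in range(0, MAX_DUPLEX_LOOP + 1):
                pi = i - 1 - l1
                if pi < 0:
                    break
                for l2 in range(0, MAX_DUPLEX_LOOP + 1):
                    pj = j - 1 - l2
                    if pj < 0:
                        break
                    if D[pi, pj] >= (1 << 20):
                        continue
                    if l1 == 0 and l2 == 0:
                        cost = int(STACK[PAIR_CODE[a[pi], b[pj]],
                                         PAIR_CODE[a[i], b[j]]])
                    elif l1 == 0 or l2 == 0:
                        cost = bulge_penalty(l1 + l2)
                    else:
                        cost = internal_penalty(l1 + l2)
                    e = min(e, int(D[pi, pj]) + cost)
            D[i, j] = e
            best = min(best, e)
    return best / 10.0


def seed_match(mirna: str, site: str) -> bool:
    """True when >=6 consecutive WC pairs fall within miRNA positions 2-8."""
    a = encode(mirna)
    b = encode(site)
    if len(a) != len(b):
        return False
    L = len(a)
    run = best = 0
    for i in range(1, min(8, L)):          # 0-based 1..7 = positions 2..8
        if PAIR_CODE[a[i], b[L - 1 - i]] in _WC_CODES:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best >= 6


def site_score(mirna: str, transcript: str, site_span, flank: int = 70,
               cutoff: float = -20.0, backend: str = "internal") -> TargetSiteScore:
    """Score one site: duplex energy plus the cost of opening the site.

    The opening cost is the MFE of the flanked context with the site forced
    unpaired minus the unconstrained MFE (clipped at zero); flanks are
    truncated at transcript ends.
    """
    s, e = site_span
    if not (0 <= s < e <= len(transcript)):
        raise ValueError("site span outside transcript")
    site = transcript[s:e].upper().replace("T", "U")
    ctx_start = max(0, s - flank)
    ctx_end = min(len(transcript), e + flank)
    context = transcript[ctx_start:ctx_end].upper().replace("T", "U")
    blocked = np.zeros(len(context), dtype=bool)
    blocked[s - ctx_start:e - ctx_start] = True
    e_free = fold(context, backend=backend).energy_kcal_mol
    e_open = fold(context, blocked=blocked, backend=backend).energy_kcal_mol
    open_cost = max(0.0, round(e_open - e_free, 1))
    duplex = duplex_energy(mirna, site)
    combined = round(duplex + open_cost, 1)
    if len(site) == len(mirna):
        paired, _ = count_pairing(mirna, site)
        seed = seed_match(mirna, site)
    else:
        paired, seed = 0, False
    return TargetSiteScore(mirna=mirna, transcript="", start=s, end=e,
                           duplex_energy=duplex, open_cost=open_cost,
                           combined_score=combined, paired_count=paired,
                           seed_matched=seed, predicted=combined <= cutoff)


def scan_transcript(mirna: str, transcript: str, name: str = "transcript",
                    flank: int = 70, cutoff: float = -20.0,
                    require_seed: bool = True) -> list[TargetSiteScore]:
    """Score every window of the transcript; position-complete seed scan.

    Windows the length of the miRNA are slid one base at a time; windows
    with a seed match (all windows when ``require_seed`` is False) are
    scored in full.  Results are sorted by combined score, best first.
    """
    L = len(mirna)
    rna = transcript.upper().replace("T", "U")
    hits = []
    for s in range(0, len(rna) - L + 1):
        window = rna[s:s + L]
        if require_seed and not seed_match(mirna, window):
            continue
        score = site_score(mirna, rna, (s, s + L), flank=flank, cutoff=cutoff)
        score.transcript = name
        hits.append(score)
    hits.sort(key=lambda h: (h.combined_score, h.start))
    return hits


def write_sites_tsv(hits, path) -> None:
    """Site report; coordinates 1-based closed on disk."""
    with open(path, "w") as fh:
        fh.write("transcript\tstart\tend\tduplex\topen\tcombined\t"
                 "paired\ttotal\tseed\tpredicted\n")
        for h in hits:
            fh.write(f"{h.transcript}\t{h.start + 1}\t{h.end}\t"
                     f"{h.duplex_energy:.1f}\t{h.open_cost:.1f}\t"
                     f"{h.combined_score:.1f}\t{h.paired_count}\t"
                     f"{len(h.mirna)}\t{int(h.seed_matched)}\t"
                     f"{int(h.predicted)}\n")
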