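"""Hairpin structure prediction and evaluation.

Minimum-free-energy folding of short RNAs (precursor-hairpin scale, 40-200
nt) under a bundled nearest-neighbor model: stacking energies for all
WC/G:U stacks plus affine penalties for hairpin, bulge, internal and
multibranch loops.  The model deliberately stops short of a partition
function: precursor validation only needs an MFE-like energy to hold
against a stability threshold, so the threshold is defined on this model's
scale and the backend is pluggable (``backend="vienna"`` delegates to
ViennaRNA when its python bindings are importable).

The module also provides structure evaluation for an arbitrary dot-bracket
string (the RNAeval-style entry point used to score proposed precursors),
stem/loop/bulge metrics for mature-region quality control, and a
max-base-pair Nussinov folder used as a quick combinatorial screen and as
an oracle anchor in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._energy import (
    BULGE_A,
    BULGE_B,
    ENC,
    HAIRPIN_A,
    HAIRPIN_B,
    INF,
    INTERNAL_A,
    INTERNAL_B,
    MAXLOOP,
    MIN_HAIRPIN,
    MULTI_A,
    MULTI_B,
    MULTI_C,
    PAIR_CODE,
    STACK,
    bulge_penalty,
    hairpin_penalty,
    internal_penalty,
)

try:  # JIT the O(n^3) fill; identical semantics without numba
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


class FoldingError(ValueError):
    """Raised for invalid sequences or malformed structures."""


def encode(sequence: str) -> np.ndarray:
    """Encode an RNA string (A/C/G/U) as an int8 array; T is accepted as U."""
    seq = sequence.upper().replace("T", "U")
    try:
        return np.array([ENC[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise FoldingError(f"invalid base {exc.args[0]!r} in sequence") from None


@njit(cache=True)
def _fill(pc, n, stack, maxloop, inf):  # pragma: no cover - exercised via fold()
    V = np.full((n, n), inf, dtype=np.int64)
    M = np.full((n, n), inf, dtype=np.int64)
    M1 = np.full((n, n), inf, dtype=np.int64)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pc[i, j] >= 0:
                best = HAIRPIN_A + HAIRPIN_B * (span - 1 - MIN_HAIRPIN)
                # interior loops (stack / bulge / internal)
                for l1 in range(0, maxloop + 1):
                    k = i + 1 + l1
                    if k >= j:
                        break
                    for l2 in range(0, maxloop + 1):
                        l = j - 1 - l2
                        if l <= k:
                            break
                        if V[k, l] >= inf:
                            continue
                        if l1 == 0 and l2 == 0:
                            e = stack[pc[i, j], pc[k, l]]
                        elif l1 == 0 or l2 == 0:
                            e = BULGE_A + BULGE_B * (l1 + l2 - 1)
                        else:
                            e = INTERNAL_A + INTERNAL_B * (l1 + l2)
                        cand = V[k, l] + e
                        if cand < best:
                            best = cand
                # multibranch loop
                for k in range(i + 1, j - 1):
                    if M[i + 1, k] < inf and M1[k + 1, j - 1] < inf:
                        cand = M[i + 1, k] + M1[k + 1, j - 1] + MULTI_A + MULTI_B
                        if cand < best:
                            best = cand
                V[i, j] = best
            # M1: exactly one helix, starting at i
            b1 = inf
            if V[i, j] < inf:
                b1 = V[i, j] + MULTI_B
            if j > i and M1[i, j - 1] < inf:
                cand = M1[i, j - 1] + MULTI_C
                if cand < b1:
                    b1 = cand
            M1[i, j] = b1
            # M: >=1 helix anywhere in [i, j]
            bm = inf
            if V[i, j] < inf:
                bm = V[i, j] + MULTI_B
            if j > i and M[i, j - 1] < inf:
                cand = M[i, j - 1] + MULTI_C
                if cand < bm:
                    bm = cand
            for k in range(i + 1, j + 1):
                if M[i, k - 1] < inf and V[k, j] < inf:
                    cand = M[i, k - 1] + V[k, j] + MULTI_B
                    if cand < bm:
                        bm = cand
            M[i, j] = bm
    W = np.zeros(n + 1, dtype=np.int64)  # W[j+1]: best energy of prefix [0, j]
    for j in range(0, n):
        best = W[j]
        for i in range(0, j):
            if V[i, j] < inf:
                cand = W[i] + V[i, j]
                if cand < best:
                    best = cand
        if V[0, j] < inf and V[0, j] < best:
            best = V[0, j]
        W[j + 1] = best
    return V, M, M1, W


def _pair_matrix(enc_seq: np.ndarray, blocked=None) -> np.ndarray:
    n = len(enc_seq)
    pc = np.full((n, n), -1, dtype=np.int8)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            pc[i, j] = PAIR_CODE[enc_seq[i], enc_seq[j]]
    if blocked is not None:
        idx = np.where(blocked)[0]
        pc[idx, :] = -1
        pc[:, idx] = -1
    return pc


def _traceback(pc, V, M, M1, W, n):
    pairs = []

    def trace_v(i, j):
        pairs.append((i, j))
        span = j - i
        e = V[i, j]
        if e == HAIRPIN_A + HAIRPIN_B * (span - 1 - MIN_HAIRPIN):
            return
        for l1 in range(0, MAXLOOP + 1):
            k = i + 1 + l1
            if k >= j:
                break
            for l2 in range(0, MAXLOOP + 1):
                l = j - 1 - l2
                if l <= k:
                    break
                if V[k, l] >= INF:
                    continue
                if l1 == 0 and l2 == 0:
                    le = STACK[pc[i, j], pc[k, l]]
                elif l1 == 0 or l2 == 0:
                    le = bulge_penalty(l1 + l2)
                else:
                    le = internal_penalty(l1 + l2)
                if V[k, l] + le == e:
                    trace_v(k, l)
                    return
        for k in range(i + 1, j - 1):
            if M[i + 1, k] + M1[k + 1, j - 1] + MULTI_A + MULTI_B == e:
                trace_m(i + 1, k)
                trace_m1(k + 1, j - 1)
                return
        raise AssertionError("traceback failed in V")

    def trace_m(i, j):
        e = M[i, j]
        if V[i, j] < INF and V[i, j] + MULTI_B == e:
            trace_v(i, j)
            return
        if j > i and M[i, j - 1] + MULTI_C == e:
            trace_m(i, j - 1)
            return
        for k in range(i + 1, j + 1):
            if M[i, k - 1] < INF and V[k, j] < INF and M[i, k - 1] + V[k, j] + MULTI_B == e:
                trace_m(i, k - 1)
                trace_v(k, j)
                return
        raise AssertionError("traceback failed in M")

    def trace_m1(i, j):
        e = M1[i, j]
        if j > i and M1[i, j - 1] + MULTI_C == e:
            trace_m1(i, j - 1)
            return
        trace_v(i, j)

    def trace_w(j):
        while j >= 0:
            if W[j + 1] == W[j]:
                j -= 1
                continue
            done = False
            for i in range(0, j + 1):
                if V[i, j] < INF and W[i] + V[i, j] == W[j + 1]:
                    trace_v(i, j)
                    j = i - 1
                    done = True
                    break
            if not done:
                raise AssertionError("traceback failed in W")

    trace_w(n - 1)
    return sorted(pairs)


@dataclass
class HairpinStructure:
    """A nested secondary structure with its energy and derived metrics."""

    sequence: str
    pairing: str
    pairs: list = field(default_factory=list)
    energy_kcal_mol: float = 0.0

    def __post_init__(self):
        if len(self.pairing) != len(self.sequence):
            raise FoldingError("pairing length != sequence length")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner(self) -> dict:
        d = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d


def pairs_to_dotbracket(pairs, n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


def dotbracket_to_pairs(db: str):
    stack, pairs = [], []
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise FoldingError(f"unbalanced ')' at position {idx}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise FoldingError(f"invalid character {ch!r} in dot-bracket")
    if stack:
        raise FoldingError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def fold(sequence: str, *, blocked=None, backend: str = "internal") -> HairpinStructure:
    """Return the minimum-energy nested structure of an RNA sequence.

    Parameters
    ----------
    sequence : RNA string over A/C/G/U (T tolerated), length 1-200.
    blocked : optional boolean mask of positions forced to stay unpaired
        (used for site-accessibility opening costs).
    backend : ``"internal"`` (default, bundled nearest-neighbor model) or
        ``"vienna"`` (ViennaRNA python bindings, if importable).
    """
    if not sequence:
        raise FoldingError("empty sequence")
    if len(sequence) > 200:
        raise FoldingError("sequence longer than 200 nt; fold windows instead")
    if backend == "vienna":
        return _fold_vienna(sequence, blocked)
    enc = encode(sequence)
    n = len(enc)
    pc = _pair_matrix(enc, blocked)
    V, M, M1, W = _fill(pc, n, STACK, MAXLOOP, INF)
    pairs = _traceback(pc, V, M, M1, W, n)
    db = pairs_to_dotbracket(pairs, n)
    return HairpinStructure(sequence=sequence, pairing=db, pairs=pairs,
                            energy_kcal_mol=W[n] / 10.0)


def _fold_vienna(sequence: str, blocked=None) -> HairpinStructure:  # pragma: no cover
    import RNA

    seq = sequence.upper().replace("T", "U")
    if blocked is not None and np.any(blocked):
        fc = RNA.fold_compound(seq)
        for i in np.where(blocked)[0]:
            fc.hc_add_up(int(i) + 1)
        db, e = fc.mfe()
    else:
        db, e = RNA.fold(seq)
    return HairpinStructure(sequence=sequence, pairing=db,
                            pairs=dotbracket_to_pairs(db),
                            energy_kcal_mol=round(float(e), 2))


def evaluate_energy(sequence: str, pairing: str) -> float:
    """Score an explicit dot-bracket structure under the bundled model.

    Decomposes the structure into hairpin, stacked-pair, bulge, internal and
    multibranch loops, and sums their energies.  The all-unpaired structure
    scores 0.0 by convention.
    """
    enc = encode(sequence)
    if len(pairing) != len(enc):
        raise FoldingError("pairing length != sequence length")
    pairs = dotbracket_to_pairs(pairing)
    for i, j in pairs:
        if PAIR_CODE[enc[i], enc[j]] < 0:
            raise FoldingError(
                f"non-canonical pair {sequence[i]}:{sequence[j]} at ({i},{j})")
        if j - i - 1 < MIN_HAIRPIN:
            raise FoldingError(f"hairpin loop shorter than {MIN_HAIRPIN} at ({i},{j})")
    total = 0
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    for i, j in pairs:
        children = _direct_children(i, j, partner)
        if not children:
            total += hairpin_penalty(j - i - 1)
        elif len(children) == 1:
            k, l = children[0]
            l1, l2 = k - i - 1, j - l - 1
            if l1 == 0 and l2 == 0:
                total += int(STACK[PAIR_CODE[enc[i], enc[j]],
                                   PAIR_CODE[enc[k], enc[l]]])
            elif l1 == 0 or l2 == 0:
                total += bulge_penalty(l1 + l2)
            else:
                total += internal_penalty(l1 + l2)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += MULTI_A + MULTI_B * (1 + len(children)) + MULTI_C * unpaired
    return total / 10.0


def _direct_children(i, j, partner):
    children = []
    k = i + 1
    while k < j:
        if k in partner and partner[k] > k:
            children.append((k, partner[k]))
            k = partner[k] + 1
        else:
            k += 1
    return children


def hairpin_metrics(structure: HairpinStructure, mature_span) -> dict:
    """Stem/loop metrics used by the precursor filters.

    Returns ``stem_pair_count`` (pairs on the path from the outermost pair of
    the main stem down to its terminal loop), ``max_defect_in_mature`` (the
    largest bulge/internal-loop whose unpaired run intersects the mature
    span) and ``n_hairpin_loops`` (terminal loops; a clean hairpin has 1).
    """
    s, e = mature_span
    if not (0 <= s < e <= len(structure.sequence)):
        raise FoldingError("mature span outside sequence")
    pairs = structure.pairs
    if not pairs:
        return {"stem_pair_count": 0, "max_defect_in_mature": e - s,
                "n_hairpin_loops": 0}
    partner = structure.partner()
    n_loops = 0
    max_defect = 0
    for i, j in pairs:
        children = _direct_children(i, j, partner)
        if not children:
            n_loops += 1
        elif len(children) == 1:
            k, l = children[0]
            l1, l2 = k - i - 1, j - l - 1
            size = l1 + l2
            if size > 0:
                runs = []
                if l1 > 0:
                    runs.append((i + 1, k - 1))
                if l2 > 0:
                    runs.append((l + 1, j - 1))
                if any(a < e and s <= b for a, b in runs):
                    max_defect = max(max_defect, size)
    # main stem: longest chain of pairs from an outermost pair to a terminal
    # loop or multiloop opening
    outer = [(i, j) for i, j in pairs
             if not any(a < i and j < b for a, b in pairs)]

    def chain_len(p):
        count = 0
        while True:
            count += 1
            children = _direct_children(p[0], p[1], partner)
            if len(children) != 1:
                return count
            p = children[0]

    stem = max(chain_len(p) for p in outer)
    return {"stem_pair_count": stem, "max_defect_in_mature": max_defect,
            "n_hairpin_loops": n_loops}


def nussinov_max_pairs(sequence: str) -> int:
    """Maximum number of nested WC/G:U pairs (min hairpin loop 3).

    A combinatorial upper bound on stem content, independent of the energy
    model; used as a quick screen and as an oracle anchor.
    """
    enc = encode(sequence)
    n = len(enc)
    if n == 0:
        return 0
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i, j - 1]
            for k in range(i, j - MIN_HAIRPIN):
                if PAIR_CODE[enc[k], enc[j]] >= 0:
                    left = dp[i, k - 1] if k > i else 0
                    inner = dp[k + 1, j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, left + inner + 1)
            dp[i, j] = best
    return int(dp[0, n - 1])
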