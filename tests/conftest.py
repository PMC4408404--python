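"""Shared fixtures and small independent oracles for the test suite."""

from __future__ import annotations

import random
from functools import lru_cache

import pytest

from lepimir.mapping import revcomp


def rna_revcomp(seq: str) -> str:
    return revcomp(seq.replace("U", "T")).replace("T", "U")


@lru_cache(maxsize=None)
def _structs(i: int, j: int, minloop: int = 3):
    """All nested pair sets over positions [i, j] (hairpin loops >= minloop)."""
    if j - i + 1 <= 0:
        return (frozenset(),)
    out = list(_structs(i + 1, j, minloop))
    for k in range(i + minloop + 1, j + 1):
        for left in _structs(i + 1, k - 1, minloop):
            for right in _structs(k + 1, j, minloop):
                out.append(left | right | {(i, k)})
    return tuple(out)


def enumerate_structures(n: int, minloop: int = 3):
    """Exhaustively enumerate every nested structure on n positions."""
    return _structs(0, n - 1, minloop)


def pairs_to_db(pairs, n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


@pytest.fixture
def rng():
    return random.Random(1234)


@pytest.fixture(scope="session")
def small_library():
    """A compact planted genome + simulated library shared across tests."""
    from lepimir import synthetic

    r = random.Random(7)
    planted = [synthetic.design_precursor(f"mir_{i:02d}", r,
                                          mature_arm=r.choice(
                                              ["five_prime", "three_prime"]))
               for i in range(10)]
    genome, truth = synthetic.make_genome(1, 15000, planted, contaminants=15,
                                          rng_seed=71)
    cfg = synthetic.ReadSimConfig(mature_depth=60, star_fraction=0.15,
                                  degradation_loci=20, degradation_depth=25,
                                  contaminant_copies=60, rng_seed=72)
    reads, prov = synthetic.simulate_reads(genome, truth, cfg)
    return {"planted": planted, "genome": genome, "truth": truth,
            "reads": reads, "provenance": prov, "cfg": cfg}
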