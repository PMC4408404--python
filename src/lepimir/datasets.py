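"""Bundled worked-example inputs for the lepidopteran miRNA analysis.

The species tree and the family presence/absence matrix reconstruct the
published survey of Lepidoptera-and-Trichoptera-specific miRNA families
across nine species (eight lepidopterans plus the caddisfly
*Glyphotaelius pellucidus* as outgroup; the low-coverage *Hepialus
sylvina* assembly is excluded from placement).  Family identities are
reproduced where the study names them (miR-2755 shared with Trichoptera;
Cam-110/Cam-154 uniting *Cameraria ohridella* and *Plutella xylostella*;
miR-6303 in the Heliconiinae+Nymphalinae ancestor; miR-2768 at the
Lepidoptera root); the remaining stem families carry plausible
miRBase-style names, as only their counts per node are published.

The miR-2768-3p / *cubitus interruptus* pair bundled here is a SYNTHETIC
stand-in: the real sequences are study data not redistributed with this
package.  The stand-in reproduces every documented property of the
interaction -- 22 nt, a fully paired seed, and exactly one base incapable
of pairing (21 of 22 pairable when G:U wobble is counted, 20 of 22 when it
is not).
"""

from __future__ import annotations

import random

import pandas as pd

from .phylo import parse_newick

#: Rooted tree of the study species (branch lengths schematic, not dated).
LEPIDOPTERA_NEWICK = (
    "(Glyphotaelius_pellucidus:3.0,"
    "((Cameraria_ohridella:2.0,Plutella_xylostella:2.0)"
    "Gracillarioidea_Yponomeutoidea:0.5,"
    "((Bombyx_mori:1.0,Manduca_sexta:1.0)Bombycoidea:0.8,"
    "(Danaus_plexippus:1.5,(Pararge_aegeria:1.2,"
    "(Heliconius_melpomene:1.0,Polygonia_c_album:1.0)"
    "Heliconiinae_Nymphalinae:0.3)Satyrine_clade:0.3)Nymphalidae:0.5)"
    "Apoditrysia:0.7)Lepidoptera:1.0)Amphiesmenoptera;"
)

SPECIES = (
    "Glyphotaelius_pellucidus", "Cameraria_ohridella", "Plutella_xylostella",
    "Bombyx_mori", "Manduca_sexta", "Danaus_plexippus", "Pararge_aegeria",
    "Heliconius_melpomene", "Polygonia_c_album",
)

#: species with small-RNA sequencing evidence (matrix code 2); the rest of a
#: family's presences rest on genome hits only (code 1)
_SEQUENCED = {"Cameraria_ohridella", "Plutella_xylostella", "Bombyx_mori",
              "Manduca_sexta", "Pararge_aegeria", "Heliconius_melpomene"}

_ALL_LEPS = SPECIES[1:]
_APODITRYSIA = ("Bombyx_mori", "Manduca_sexta", "Danaus_plexippus",
                "Pararge_aegeria", "Heliconius_melpomene", "Polygonia_c_album")

#: family -> present species; counts per origin node follow the published
#: figures (1 shared with Trichoptera, 11 at the Lepidoptera root, 2 at the
#: Cameraria+Plutella node, 3 on the Apoditrysia stem, 1 in the
#: Heliconiinae+Nymphalinae ancestor); Par-471's absence from Manduca is a
#: lineage-specific loss example.
FAMILY_PRESENCE = {
    "miR-2755": SPECIES,
    "miR-2756": _ALL_LEPS,
    "miR-2757": _ALL_LEPS,
    "miR-2758": _ALL_LEPS,
    "miR-2761": _ALL_LEPS,
    "miR-2762": _ALL_LEPS,
    "miR-2763": _ALL_LEPS,
    "miR-2765": _ALL_LEPS,
    "miR-2766": _ALL_LEPS,
    "miR-2768": _ALL_LEPS,
    "miR-2796": _ALL_LEPS,
    "Par-471": tuple(s for s in _ALL_LEPS if s != "Manduca_sexta"),
    "miR-2759": _APODITRYSIA,
    "miR-2760": _APODITRYSIA,
    "miR-2764": _APODITRYSIA,
    "Cam-110": ("Cameraria_ohridella", "Plutella_xylostella"),
    "Cam-154": ("Cameraria_ohridella", "Plutella_xylostella"),
    "miR-6303": ("Heliconius_melpomene", "Polygonia_c_album"),
}

#: the 25 precursors shared by >=2 species across Lepidoptera+Trichoptera,
#: before quality screening
LOW_CONFIDENCE_REMOVALS = ("miR-2739", "miR-3389", "miR-2733",
                           "miR-6495", "miR-6496", "miR-6497")
UNCONFIRMED_HOMOLOGY = ("miR-2779",)
SHARED_PRECURSORS = tuple(FAMILY_PRESENCE) + UNCONFIRMED_HOMOLOGY + \
    LOW_CONFIDENCE_REMOVALS


def species_tree():
    """The rooted nine-species tree with labelled internal nodes."""
    return parse_newick(LEPIDOPTERA_NEWICK)


def presence_matrix() -> pd.DataFrame:
    """Family x species matrix, cells 0/1/2 (absent/genomic/sequenced)."""
    rows = {}
    for family, present in FAMILY_PRESENCE.items():
        rows[family] = {sp: (2 if sp in _SEQUENCED else 1) if sp in present
                        else 0 for sp in SPECIES}
    return pd.DataFrame.from_dict(rows, orient="index")[list(SPECIES)]


def retained_for_genome_search() -> tuple[str, ...]:
    """Shared precursors surviving the low-confidence screen (19 of 25)."""
    return tuple(f for f in SHARED_PRECURSORS
                 if f not in LOW_CONFIDENCE_REMOVALS)


def placed_families() -> tuple[str, ...]:
    """Families that enter phylogenetic placement (homology-confirmed)."""
    return tuple(f for f in retained_for_genome_search()
                 if f not in UNCONFIRMED_HOMOLOGY)


# --- synthetic miR-2768-3p <-> ci stand-in ---------------------------------
# 22 nt; in the ungapped antiparallel register the site pairs Watson-Crick at
# 20 positions, G:U at one (miRNA position 13) and not at all at one (miRNA
# position 18); the seed (positions 2-8) is fully Watson-Crick paired.
SYNTHETIC_MIR2768_3P = "UGAGGUCAUACGGUUCAUCAGA"
SYNTHETIC_CI_SITE = "UCUGCUGAAUCGUAUGACCUCA"


def synthetic_ci_transcript(seed: int = 20768, length: int = 360):
    """A synthetic coding-sequence context with the ci site planted mid-CDS.

    Returns ``(transcript_rna, site_span)``; the flanking sequence is random
    and the site placement deterministic for a given seed.
    """
    rng = random.Random(seed)
    site = SYNTHETIC_CI_SITE
    flank_len = (length - len(site)) // 2
    left = "".join(rng.choice("ACGU") for _ in range(flank_len))
    right = "".join(rng.choice("ACGU") for _ in range(length - flank_len - len(site)))
    transcript = left + site + right
    return transcript, (flank_len, flank_len + len(site))
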