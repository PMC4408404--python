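"""Synthetic genomes, read libraries and gain/loss histories.

Everything downstream of raw data is testable without downloads: this
module plants designed precursor hairpins in an i.i.d.-uniform background
genome, simulates small-RNA libraries over them (mature reads with
controllable 5'-end jitter, star-arm reads, degradation fragments with
uniform 5' starts, and rRNA-like repeat contaminants), and simulates miRNA
family gain/loss histories on a species tree with known birth nodes.

Ground truth travels with every artifact: genomes carry a locus truth
table, libraries carry a per-read provenance sidecar, and histories record
each family's birth branch, so recovery experiments (discovery precision/
recall, origin-assignment accuracy) reduce to table joins.

Sequences are DNA on disk; the U<->T conversion happens at the folding
boundary.  Read qualities are written as constant 'I' (Phred 40) -- the
annotation filters are sequence-based and ignore qualities.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import pandas as pd

from .folding import fold
from .mapping import revcomp

#: fixed 120-nt rRNA-like repeat unit used for contaminant insertions;
#: GC-rich with internal repeats, deliberately un-hairpin-like.
RRNA_UNIT = (
    "GGCGACCTGGGAAGGTAGTGACGAAAAATAGCGGCGACCTGGGAAGGTAGTGACGAAAAAT"
    "AGCGCGCAAGGCTGAAACTTAAAGGAATTGACGGAAGGGCACCACCAGGAGTGGAGCCT"
)

JITTER_OFFSETS = (-2, -1, 0, 1, 2)


class GenerationError(RuntimeError):
    pass


class ConfigError(ValueError):
    pass


@dataclass
class PlantedMiRNA:
    """A designed precursor hairpin with known arms and genomic locus."""

    name: str
    precursor_seq: str          # RNA, mature + loop + star (5' arm) or reverse
    mature_seq: str             # RNA, 18-24 nt
    mature_arm: str             # "five_prime" | "three_prime"
    genome_locus: Optional[tuple] = None   # (contig, start, end, strand)
    true_energy_pass: bool = True
    mature_offset: int = 0      # mature start within the precursor
    star_offset: int = 0


@dataclass
class ReadSimConfig:
    mature_depth: int = 100
    star_fraction: float = 0.1
    five_prime_jitter_modal_mass: float = 0.95
    degradation_loci: int = 0
    degradation_depth: int = 50
    contaminant_copies: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.star_fraction <= 1.0:
            raise ConfigError("star_fraction must be in [0, 1]")
        if not 0.0 <= self.five_prime_jitter_modal_mass <= 1.0:
            raise ConfigError("jitter modal mass must be in [0, 1]")


def design_precursor(name: str, rng: random.Random, mature_len: int = 22,
                     loop_len: int = 8, n_mismatches: int = 2,
                     mature_arm: str = "five_prime") -> PlantedMiRNA:
    """Design a hairpin precursor around a random GC-biased mature sequence.

    The star arm is the reverse complement of the mature arm with up to two
    engineered mismatches, so the precursor folds into a single stable stem
    by construction; ``true_energy_pass`` records whether the designed fold
    clears the stability criteria (it does for <=2 mismatches).
    """
    if n_mismatches > 2:
        raise ConfigError("designed precursors allow at most 2 mismatches")
    from .folding import hairpin_metrics

    for _attempt in range(50):
        mature = "".join(rng.choice("ACGUGC") for _ in range(mature_len))
        star = list(revcomp(mature.replace("U", "T")).replace("T", "U"))
        # mismatches kept central and separated so the duplex stays one
        # clean stem with small (1x1) interior defects
        positions = []
        while len(positions) < n_mismatches:
            pos = rng.randrange(5, mature_len - 6)
            if all(abs(pos - p) >= 4 for p in positions):
                positions.append(pos)
        for pos in positions:
            mature_partner = mature[mature_len - 1 - pos]
            bad = {"A": "U", "C": "G", "G": "CU", "U": "AG"}[mature_partner]
            star[pos] = rng.choice([b for b in "ACGU" if b not in bad])
        star = "".join(star)
        loop = "".join(rng.choice("AUC") for _ in range(loop_len))
        if mature_arm == "five_prime":
            precursor = mature + loop + star
            moff, soff = 0, mature_len + loop_len
        else:
            precursor = star + loop + mature
            moff, soff = mature_len + loop_len, 0
        structure = fold(precursor)
        metrics = hairpin_metrics(structure, (moff, moff + mature_len))
        passes = (structure.energy_kcal_mol < -18.0
                  and metrics["stem_pair_count"] >= 18
                  and metrics["max_defect_in_mature"] <= 4
                  and metrics["n_hairpin_loops"] == 1)
        if passes:
            break
    return PlantedMiRNA(name=name, precursor_seq=precursor, mature_seq=mature,
                        mature_arm=mature_arm, true_energy_pass=passes,
                        mature_offset=moff, star_offset=soff)


def make_genome(n_contigs: int, contig_len: int, planted: list[PlantedMiRNA],
                contaminants: int = 0, rng_seed: int = 0):
    """Embed planted precursors and contaminant repeats in a random genome.

    Returns ``(genome, truth)``: contig-name -> DNA string, and a locus
    truth table (one row per planted precursor or contaminant copy).
    Placement is collision-free; more than 100 failed attempts for one
    element raise a generation error naming the contig.
    """
    names = [p.name for p in planted]
    if len(set(names)) != len(names):
        raise GenerationError("planted miRNA names must be unique")
    if planted and contig_len < 10 * max(len(p.precursor_seq) for p in planted):
        raise GenerationError("contig_len must be >= 10x precursor length")
    rng = random.Random(rng_seed)
    contigs = {f"contig_{i + 1}": list("".join(rng.choice("ACGT") for _ in range(contig_len)))
               for i in range(n_contigs)}
    occupied: dict[str, list] = {c: [] for c in contigs}
    truth_rows = []

    def place(element_name: str, dna: str, kind: str, extra=None):
        for _ in range(100):
            contig = rng.choice(list(contigs))
            start = rng.randrange(0, contig_len - len(dna))
            end = start + len(dna)
            if any(s < end and start < e for s, e in occupied[contig]):
                continue
            strand = rng.choice("+-")
            ins = dna if strand == "+" else revcomp(dna)
            contigs[contig][start:end] = list(ins)
            occupied[contig].append((start, end))
            row = {"name": element_name, "kind": kind, "contig": contig,
                   "start": start, "end": end, "strand": strand}
            if extra:
                row.update(extra)
            truth_rows.append(row)
            return contig, start, end, strand
        raise GenerationError(
            f"could not place {element_name} without collision on "
            f"{'/'.join(contigs)} after 100 attempts")

    for p in planted:
        dna = p.precursor_seq.replace("U", "T")
        locus = place(p.name, dna, "mirna", {
            "mature_offset": p.mature_offset,
            "mature_len": len(p.mature_seq),
            "star_offset": p.star_offset,
            "star_len": len(p.mature_seq),  # star = rc(mature) +- mismatches
            "energy_pass": p.true_energy_pass,
        })
        p.genome_locus = locus
    for i in range(contaminants):
        place(f"rrna_{i + 1}", RRNA_UNIT, "contaminant")
    genome = {c: "".join(seq) for c, seq in contigs.items()}
    truth = pd.DataFrame(truth_rows)
    return genome, truth


def _genomic_read(genome, contig, start, length, strand):
    seq = genome[contig][max(0, start):start + length]
    if len(seq) < length:
        return None
    return seq if strand == "+" else revcomp(seq)


def _sample_jitter(rng, modal_mass: float) -> int:
    if rng.random() < modal_mass:
        return 0
    return rng.choice([o for o in JITTER_OFFSETS if o != 0])


def simulate_reads(genome: dict[str, str], truth: pd.DataFrame,
                   cfg: ReadSimConfig):
    """Simulate a small-RNA library over a planted genome.

    Returns ``(reads, provenance)``: a list of (read_id, DNA sequence) and a
    sidecar table recording each read's source (mature / star /
    degradation / contaminant) and origin.  Mature reads start at the
    mature 5' end plus a jitter offset (modal offset 0 with the configured
    modal mass) and have lengths 20-23; star reads are drawn from the
    opposite arm at ``star_fraction`` of the mature depth; degradation
    fragments have uniform 5' starts on one strand of random windows;
    contaminant reads are fragments of the rRNA-like repeat unit.
    """
    rng = random.Random(cfg.rng_seed)
    reads = []
    prov = []
    serial = 0

    def emit(seq, source, origin, offset=0):
        nonlocal serial
        serial += 1
        rid = f"sim_{serial}"
        reads.append((rid, seq))
        prov.append({"read_id": rid, "source": source, "origin": origin,
                     "offset": offset})

    mirna_rows = truth[truth["kind"] == "mirna"] if len(truth) else truth
    for _, row in mirna_rows.iterrows():
        contig, strand = row["contig"], row["strand"]
        start, end = int(row["start"]), int(row["end"])
        mature_offset = int(row["mature_offset"])
        star_offset = int(row["star_offset"])
        # genomic coordinates of the mature 5' end depend on strand
        for _ in range(int(cfg.mature_depth)):
            off = _sample_jitter(rng, cfg.five_prime_jitter_modal_mass)
            length = rng.randrange(20, 24)
            if strand == "+":
                gstart = start + mature_offset + off
                seq = _genomic_read(genome, contig, gstart, length, "+")
            else:
                gend = end - mature_offset - off
                seq = _genomic_read(genome, contig, gend - length, length, "-")
            if seq:
                emit(seq, "mature", row["name"], off)
        n_star = sum(rng.random() < cfg.star_fraction
                     for _ in range(int(cfg.mature_depth)))
        for _ in range(n_star):
            off = _sample_jitter(rng, cfg.five_prime_jitter_modal_mass)
            length = rng.randrange(20, 24)
            if strand == "+":
                gstart = start + star_offset + off
                seq = _genomic_read(genome, contig, gstart, length, "+")
            else:
                gend = end - star_offset - off
                seq = _genomic_read(genome, contig, gend - length, length, "-")
            if seq:
                emit(seq, "star", row["name"], off)

    window = 150
    for i in range(int(cfg.degradation_loci)):
        contig = rng.choice(list(genome))
        wstart = rng.randrange(0, len(genome[contig]) - window)
        strand = rng.choice("+-")
        origin = f"deg_{i + 1}:{contig}:{wstart}-{wstart + window}:{strand}"
        for _ in range(int(cfg.degradation_depth)):
            length = rng.randrange(18, 25)
            s = rng.randrange(wstart, wstart + window - length)
            seq = _genomic_read(genome, contig, s, length, strand)
            if seq:
                emit(seq, "degradation", origin)

    for _ in range(int(cfg.contaminant_copies)):
        length = rng.randrange(20, 24)
        s = rng.randrange(0, len(RRNA_UNIT) - length)
        emit(RRNA_UNIT[s:s + length], "contaminant", "rrna_unit")

    return reads, pd.DataFrame(prov)


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_genome_fasta(genome: dict[str, str], path, wrap: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


@dataclass
class GainLossHistory:
    """Simulated family histories with known birth branches."""

    tree: dendropy.Tree
    families: list = field(default_factory=list)  # dicts: name, birth_node, lost, present


def simulate_gain_loss(tree: dendropy.Tree, n_families: int,
                       loss_prob_per_branch: float = 0.0, rng_seed: int = 0):
    """Simulate single-gain families with independent per-branch losses.

    Each family's birth branch is drawn with probability proportional to
    branch length (uniform, with a warning, when lengths are missing); a
    loss on a branch removes the whole subtree below it.  Families losing
    every descendant leaf are re-drawn so each reported family has a
    non-empty presence set.  Returns ``(history, matrix)`` where the matrix
    codes presence as sequenced (2).
    """
    if not 0.0 <= loss_prob_per_branch < 1.0:
        raise ConfigError("loss_prob_per_branch must be in [0, 1)")
    from .phylo import ensure_node_labels

    ensure_node_labels(tree)
    rng = random.Random(rng_seed)
    nodes = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    lengths = [n.edge.length for n in nodes]
    if any(l is None for l in lengths):
        warnings.warn("tree lacks branch lengths; birth branches drawn uniformly")
        weights = [1.0] * len(nodes)
    else:
        weights = [max(float(l), 0.0) for l in lengths]
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    history = GainLossHistory(tree=tree)
    rows = {}
    for i in range(n_families):
        name = f"fam_{i + 1:04d}"
        for _attempt in range(1000):
            birth = rng.choices(nodes, weights=weights)[0]
            lost_leaves: set[str] = set()

            def descend(node, alive=True):
                for child in node.child_nodes():
                    child_alive = alive and not (rng.random() < loss_prob_per_branch)
                    if child.is_leaf():
                        if not child_alive:
                            lost_leaves.add(child.taxon.label)
                    else:
                        descend(child, child_alive)

            clade = {l.taxon.label for l in birth.leaf_iter()}
            if loss_prob_per_branch > 0:
                descend(birth)
            present = clade - lost_leaves
            if present:
                break
        history.families.append({"name": name, "birth_node": birth.label,
                                 "lost": sorted(lost_leaves & clade),
                                 "present": sorted(present)})
        rows[name] = {leaf: (2 if leaf in present else 0) for leaf in leaves}
    matrix = pd.DataFrame.from_dict(rows, orient="index")[leaves]
    return history, matrix
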