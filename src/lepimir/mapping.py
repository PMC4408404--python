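"""Seed-and-verify read mapping against small genome assemblies.

An exact k-mer positional index over the genome with Hamming-distance
verification of full-length hits on both strands.  This deliberately
desk-scale mapper replaces an external short-read aligner: with the seed
length at most ``(L-1)//2`` for the shortest read L, every alignment with
<=1 mismatch contains an exact seed, so the mapper is complete for the
default mismatch allowance (and is checked against a brute-force
sliding-window oracle in tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

_COMP = str.maketrans("ACGTN", "TGCAN")

#: loci above this are reported but the read is flagged repeat-derived
MAX_MULTIMAP = 10


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReadMapping:
    """One placement of a read on the genome (0-based half-open)."""

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    mismatches: int
    count: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeIndex:
    """Exact k-mer positional index over forward-strand contigs."""

    def __init__(self, genome: dict[str, str], k: int = 9):
        if len(set(genome)) != len(genome):
            raise ValueError("duplicate contig names")
        self.k = k
        self.genome = {name: seq.upper().replace("U", "T")
                       for name, seq in genome.items()}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.genome.items():
            if len(seq) < k:
                warnings.warn(f"contig {name} shorter than k={k}; skipped")
                continue
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos:pos + k], []).append((name, pos))

    def seed_hits(self, kmer: str):
        return self._index.get(kmer, ())


def read_genome_fasta(path) -> dict[str, str]:
    """Load a genome FASTA; duplicate contig names are an error."""
    from Bio import SeqIO

    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate contig name {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def build_index(genome: dict[str, str], k: int = 9) -> GenomeIndex:
    return GenomeIndex(genome, k=k)


def _hamming(a: str, b: str, limit: int) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def map_read(read, index: GenomeIndex, max_mismatches: int = 1) -> list[ReadMapping]:
    """All loci where the read or its reverse complement matches.

    Returns every placement with at most ``max_mismatches`` substitutions,
    sorted by (contig, start, strand).  An empty list means the read is
    discarded downstream.
    """
    seq = read.sequence if hasattr(read, "sequence") else str(read)
    read_id = getattr(read, "id", seq)
    count = getattr(read, "count", 1)
    seq = seq.upper().replace("U", "T")
    k = index.k
    if len(seq) < k:
        raise ValueError("read shorter than index seed length")
    found = {}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for off in range(len(s) - k + 1):
            for contig, pos in index.seed_hits(s[off:off + k]):
                start = pos - off
                end = start + len(s)
                ref = index.genome[contig]
                if start < 0 or end > len(ref):
                    continue
                key = (contig, start, strand)
                if key in found:
                    continue
                mm = _hamming(s, ref[start:end], max_mismatches)
                if mm <= max_mismatches:
                    found[key] = ReadMapping(read_id=read_id, contig=contig,
                                             start=start, end=end,
                                             strand=strand, mismatches=mm,
                                             count=count)
    return [found[key] for key in sorted(found)]


def map_reads(reads, index: GenomeIndex, max_mismatches: int = 1):
    """Map a collapsed read set; returns (mappings, high_multimap_read_ids)."""
    mappings: list[ReadMapping] = []
    high_multimap: set[str] = set()
    for read in reads:
        hits = map_read(read, index, max_mismatches)
        if len(hits) > MAX_MULTIMAP:
            high_multimap.add(getattr(read, "id", read))
            hits = hits[:MAX_MULTIMAP]
        mappings.extend(hits)
    return mappings, high_multimap


def write_mappings_tsv(mappings, path) -> None:
    """Tab-separated report; coordinates are 1-based closed on disk."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tread_id\tcount\tmismatches\n")
        for m in mappings:
            fh.write(f"{m.contig}\t{m.start + 1}\t{m.end}\t{m.strand}\t"
                     f"{m.read_id}\t{m.count}\t{m.mismatches}\n")
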