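"""Raw small-RNA reads to a non-redundant, length-filtered read set.

Adapter trimming, redundancy collapsing and the 18-24 nt length window are
the first stages of the annotation pipeline: small RNA libraries are
dominated by identical mature-miRNA copies, so all downstream work happens
on unique sequences carrying their multiplicities.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from typing import Iterable, Optional

from Bio import SeqIO

#: reads strictly shorter than 18 or longer than 24 nt are discarded;
#: 18 and 24 themselves are kept
MIN_LEN = 18
MAX_LEN = 24


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with its multiplicity in the library."""

    sequence: str
    count: int
    id: str

    def __len__(self) -> int:
        return len(self.sequence)


def trim_adapter(read: str, adapter: str, min_overlap: int = 6):
    """Remove a 3' adapter from a read.

    The suffix is cut at the first position where at least ``min_overlap``
    bases of the adapter prefix match with at most one mismatch.  Reads with
    no adapter occurrence are kept whole.

    Returns ``(trimmed, None)`` on success or ``(None, reason)`` when the
    read is rejected (empty input, or nothing left after trimming).
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    if not read:
        return None, "empty"
    read = read.upper()
    adapter = adapter.upper()
    for pos in range(len(read)):
        overlap = min(len(adapter), len(read) - pos)
        if overlap < min_overlap:
            break
        mismatches = sum(1 for a, b in zip(read[pos:pos + overlap], adapter)
                         if a != b)
        if mismatches <= 1:
            if pos == 0:
                return None, "empty"
            return read[:pos], None
    return read, None


def collapse_reads(reads: Iterable[str]) -> list[CollapsedRead]:
    """Collapse a read list to unique sequences with counts.

    Records are ranked by descending count (ties broken lexicographically)
    and named ``seq_<rank>_x<count>``; total counts equal the input size.
    """
    counts = Counter(r.upper() for r in reads)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [CollapsedRead(sequence=seq, count=c, id=f"seq_{rank}_x{c}")
            for rank, (seq, c) in enumerate(ranked, start=1)]


def length_filter(reads: Iterable[CollapsedRead], min_len: int = MIN_LEN,
                  max_len: int = MAX_LEN) -> list[CollapsedRead]:
    """Retain reads with min_len <= length <= max_len (bounds inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    return [r for r in reads if min_len <= len(r.sequence) <= max_len]


def read_fastq(path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def read_fasta_counts(path) -> list[CollapsedRead]:
    """Read a collapsed FASTA written by :func:`write_collapsed_fasta`."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1]) if "_x" in rec.id else 1
        out.append(CollapsedRead(sequence=str(rec.seq).upper(), count=count,
                                 id=rec.id))
    return out


def write_collapsed_fasta(reads: Iterable[CollapsedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")


def preprocess(raw_reads: Iterable[str], adapter: Optional[str] = None,
               min_overlap: int = 6, min_len: int = MIN_LEN,
               max_len: int = MAX_LEN):
    """Full preprocessing stage; returns (collapsed_filtered, stage_counts)."""
    raw = list(raw_reads)
    if adapter is not None:
        trimmed = []
        for r in raw:
            t, _reason = trim_adapter(r, adapter, min_overlap)
            if t is not None:
                trimmed.append(t)
    else:
        trimmed = raw
    collapsed = collapse_reads(trimmed)
    kept = length_filter(collapsed, min_len, max_len)
    counts = {
        "raw_reads": len(raw),
        "trimmed_reads": len(trimmed),
        "unique_reads": len(collapsed),
        "retained_unique": len(kept),
        "retained_total": sum(r.count for r in kept),
    }
    return kept, counts
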