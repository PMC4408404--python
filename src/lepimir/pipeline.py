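"""End-to-end orchestration: preprocess -> map -> discover -> annotate.

A single configuration object carries every stage threshold next to its
reference default, and a run produces per-stage artifacts plus a
machine-readable summary whose counts telescope (each stage's output is
the next stage's input).  Runs are fully deterministic for a fixed seed;
the summary embeds a hash of the effective configuration so reruns can be
compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import discovery, homology, mapping, preprocess

#: reference defaults for every tunable, recorded beside the active values
DEFAULTS = {
    "adapter": None,
    "min_len": 18, "max_len": 24,
    "seed_k": 9, "max_mismatches": 1,
    "window": 80,
    "energy_max": -18.0, "min_stem_pairs": 18, "max_mature_defect": 4,
    "min_homogeneity": 0.8, "min_mature_reads": 5,
    "min_report_score": 50,
    "rng_seed": 0,
}


@dataclass
class RunConfig:
    fastq: Optional[str] = None
    genome: Optional[str] = None
    reference: Optional[str] = None          # known precursors FASTA
    decoys: dict = field(default_factory=dict)  # set name -> FASTA path
    outdir: str = "lepimir_out"
    adapter: Optional[str] = DEFAULTS["adapter"]
    min_len: int = DEFAULTS["min_len"]
    max_len: int = DEFAULTS["max_len"]
    seed_k: int = DEFAULTS["seed_k"]
    max_mismatches: int = DEFAULTS["max_mismatches"]
    window: int = DEFAULTS["window"]
    energy_max: float = DEFAULTS["energy_max"]
    min_stem_pairs: int = DEFAULTS["min_stem_pairs"]
    max_mature_defect: int = DEFAULTS["max_mature_defect"]
    min_homogeneity: float = DEFAULTS["min_homogeneity"]
    min_report_score: int = DEFAULTS["min_report_score"]
    rng_seed: int = DEFAULTS["rng_seed"]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # outdir is bookkeeping, not analysis configuration: reruns into a
        # different directory must hash (and summarise) identically
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunSummary:
    counts: dict = field(default_factory=dict)
    rejections: dict = field(default_factory=dict)
    config_hash: str = ""
    version: str = "0.1.0"

    def to_json(self) -> str:
        return json.dumps({"counts": self.counts, "rejections": self.rejections,
                           "config_hash": self.config_hash,
                           "version": self.version}, sort_keys=True, indent=2)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_fasta_dict(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: RunConfig, raw_reads=None, genome=None) -> RunSummary:
    """Run the full annotation pipeline and write artifacts to ``outdir``.

    ``raw_reads`` (list of sequences) and ``genome`` (contig dict) may be
    passed in memory; otherwise they are read from the configured FASTQ and
    FASTA paths.  Returns the run summary; artifacts written are the
    collapsed read set, the mapping table, a GFF3 of accepted loci, the
    per-candidate verdict table and ``summary.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(config_hash=config.config_hash())

    try:
        if raw_reads is None:
            raw_reads = preprocess.read_fastq(config.fastq) if config.fastq else []
        if genome is None:
            if not config.genome:
                raise StageError("map", "no genome provided")
            genome = mapping.read_genome_fasta(config.genome)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input", str(exc)) from exc

    kept, pp_counts = preprocess.preprocess(
        raw_reads, adapter=config.adapter, min_len=config.min_len,
        max_len=config.max_len)
    preprocess.write_collapsed_fasta(kept, outdir / "collapsed.fasta")
    summary.counts.update(pp_counts)

    index = mapping.build_index(genome, k=config.seed_k)
    mappings, high_multimap = mapping.map_reads(kept, index,
                                                config.max_mismatches)
    mapping.write_mappings_tsv(mappings, outdir / "mappings.tsv")
    mapped_ids = {m.read_id for m in mappings}
    summary.counts["mapped_unique_reads"] = len(mapped_ids)
    summary.counts["unaligned_discarded"] = len(kept) - len(mapped_ids)
    summary.counts["high_multimap_reads"] = len(high_multimap)

    accepted, all_cands = discovery.discover(
        mappings, genome, high_multimap=high_multimap, window=config.window,
        energy_max=config.energy_max, min_stem_pairs=config.min_stem_pairs,
        max_mature_defect=config.max_mature_defect,
        min_homogeneity=config.min_homogeneity)
    discovery.write_gff3(accepted, outdir / "candidates.gff3")
    discovery.write_candidate_fasta(accepted, outdir / "candidates.fasta")
    discovery.write_verdicts_tsv(all_cands, outdir / "verdicts.tsv")
    summary.counts["candidates_proposed"] = len(all_cands)
    summary.counts["candidates_accepted"] = len(accepted)
    for fname in discovery.FILTER_ORDER:
        summary.rejections[fname] = sum(
            1 for c in all_cands
            if (v := c.verdict(fname)) is not None and not v.passed)

    conserved = novel = 0
    if config.reference and accepted:
        scoring = homology.AlignmentScoring(
            min_report_score=config.min_report_score)
        cand_seqs = {f"cand_{i + 1}": c.sequence.replace("U", "T")
                     for i, c in enumerate(accepted)}
        reference = _load_fasta_dict(config.reference)
        verified, novel_names = homology.reciprocal_best(cand_seqs, reference,
                                                         scoring)
        decoy_sets = {name: _load_fasta_dict(p) if Path(p).exists() else {}
                      for name, p in config.decoys.items()}
        flags, _warn = homology.screen_contaminants(
            {n: cand_seqs[n] for n in novel_names}, decoy_sets, scoring)
        conserved = len(verified)
        novel = len([n for n in novel_names if n not in flags])
        summary.counts["contaminant_flagged"] = len(flags)
    else:
        novel = len(accepted)
    summary.counts["conserved_mirnas"] = conserved
    summary.counts["novel_mirnas"] = novel
    summary.counts["total_mirnas"] = conserved + novel

    (outdir / "summary.json").write_text(summary.to_json())
    return summary
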