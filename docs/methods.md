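# Methods

## Scope and model

The package implements a conservative miRNA annotation pipeline for small
RNA sequencing data, a Dollo-style mapping of miRNA family origins onto a
species phylogeny, and an accessibility-aware (ΔΔG) target-site score.
The guiding assumption throughout is that a genuine miRNA leaves a
characteristic footprint: a stable single-stem hairpin precursor, a sharp
(5′-homogeneous) stack of mature reads on one arm, and star reads on the
other arm positioned where the structure says the processing machinery
leaves them. Degradation fragments of longer transcripts violate one or
more of these; repeat-derived sequences betray themselves by multi-mapping.

## Folding engine

`lepimir.folding` implements minimum-free-energy folding of short RNAs
(≤200 nt) by a Zuker-style dynamic program over a bundled nearest-neighbor
parameter set: a 6×6 stacking table over {AU, UA, CG, GC, GU, UG} with
Turner-style magnitudes, and affine penalties for hairpin loops
(5.2 + 0.2·(n−3) kcal/mol), bulges (3.8 + 0.2·(n−1)), internal loops
(1.5 + 0.3·n) and multibranch loops (3.4 closing + 0.4/branch +
0.1/unpaired nt). Interior loops are capped at 15 unpaired nt per side.
Energies are int arithmetic in tenths of kcal/mol; the O(n³) fill is
numba-compiled with a pure-python fallback of identical semantics.

Design choices worth knowing:

- **No partition function.** The pipeline uses energies only as a
  stability threshold, so MFE suffices. The −18 kcal/mol precursor
  threshold is defined on this model's scale; the backend is pluggable
  (`backend="vienna"` uses ViennaRNA where available) but the bundled
  model is the default and the reference for all thresholds.
- **G:U wobble pairs throughout**, in folding, duplexes and pairing
  counts (toggleable where it matters scientifically, e.g.
  `count_pairing(allow_GU=False)`).
- **`evaluate_energy`** scores any explicit nested dot-bracket under the
  same tables (loop decomposition), so fold results are internally
  checkable: tests assert `evaluate_energy(seq, fold(seq).pairing)`
  equals the DP energy, and that the DP energy equals the minimum over
  *all* nested structures enumerated exhaustively for n ≤ 12.
- **`nussinov_max_pairs`** is a separate combinatorial folder (maximum
  pairs, min hairpin loop 3). It is deliberately not the MFE engine — an
  energy model legitimately leaves weak stems unpaired — and both are
  validated against the same exhaustive enumeration.
- "At least 18 paired bases on the main stem" is interpreted as 18 base
  *pairs* on the path from the outermost pair to the terminal loop;
  `min_stem_pairs` is configurable for the 9-pair reading.
- "Large" mature-region defects default to >4 unpaired nt in a
  bulge/internal loop intersecting the mature span, a typical tolerance
  in miRNA annotation practice.

## Discovery

Read stacks are clusters of same-strand mappings seeded greedily at the
most abundant unassigned read (the presumptive mature product); a mapping
joins when it overlaps the anchor by ≥50% of the shorter read. Each stack
is excised in two 80-nt windows (stack as 5′ arm, stack as 3′ arm), both
folded, the lower-energy placement kept. The window is then trimmed to the
top-level helix best covering the mature span and refolded — without this,
random flanking genomic sequence routinely folds into a second small stem
and no candidate would ever show exactly one terminal loop.

Filters run in a fixed order (repeat, structure, 5′ homogeneity, arm
support) and every candidate records a verdict per filter, so the verdict
table is a complete audit trail. Two evidentiary guards supplement the
headline thresholds:

- **Minimum mature support (5 weighted reads).** A homogeneity ratio
  computed from one or two reads is vacuous (h = 1 by arithmetic); sparse
  degradation stacks otherwise slip through on a technicality. Five reads
  is the smallest support on which the modal-share test is meaningful at
  the 0.8 threshold.
- **Star-position consistency (±7 nt).** Opposite-arm reads count as star
  evidence only when they start near the structure-predicted star span.
  Processing from a duplex fixes the star 5′ end; uniformly placed
  fragments on the far arm are degradation, not processing evidence. The
  tolerance covers 5′ jitter plus the coordinate slack introduced by
  stem trimming.

Candidates anchored on reads with >10 genomic loci are rejected as
repeat-derived. Deduplication keeps, per strand, the highest-count
candidate among overlapping loci (ties to the lower start coordinate).

## Homology and contaminant screening

Local alignment is seeded (an exact 4-mer word must exist) and then scored
by affine-gap Smith–Waterman with match +5, mismatch −4 and gap cost
8 + 6·length — the BLASTn parameterisation appropriate for short, weakly
conserved precursors. E-values are not computed; at desk scale a raw-score
floor (default 50, ≈10 net matching bases) is transparent and sufficient.
Conserved/novel classification requires a *reciprocal* best hit — each
sequence the other's unambiguous top scorer — which makes the verified set
a partial matching; ties are rejected as ambiguous rather than guessed.
Decoy screening flags any candidate scoring against repeat, structural-RNA
or bacterial decoy sets; empty decoy sets are skipped with a recorded
warning.

## Phylogenetic placement

A family arises once, at the MRCA of the species carrying it (both
genomic-only and sequencing evidence count as presence; the distinction is
carried through to reports). This "latest possible node of origin" is a
lower bound on family age: with unobserved losses the true origin can only
be the assigned node or an ancestor, which the gain/loss simulation
verifies as a property (assigned origin ∈ {birth node} ∪ descendants, and
exactly the birth node when losses are disabled). Unrooted trees (basal
polytomies) are rejected rather than auto-rooted, since the MRCA is
undefined without a root. Losses are reported per family as absent leaves
under the origin, each flagged `genome-completeness-limited` because an
absence call rests on an assembly, not on positive evidence.

The bundled nine-species tree and 18-family matrix in `lepimir.datasets`
reconstruct the published lepidopteran survey from its figure-encoded
summary; family identities are reproduced where named (miR-2755, Cam-110,
Cam-154, miR-6303, miR-2768), the remaining stem families carry
plausible miRBase-style placeholder names, and branch lengths are
schematic. The 25/19/18 shared-precursor bookkeeping is encoded with the
six named low-confidence removals and the one homology-unconfirmed
sequence (miR-2779).

## Target scoring

`ΔΔG = ΔG_duplex + ΔG_open`. The duplex term is an optimal antiparallel
hybridization energy (two-strand DP, same stacking table, bulge/internal
loops capped at 8 nt per side, zero initiation — hence ≤0 whenever any
pair forms). The opening term is the MFE of the site ±70 nt of context
with the site constrained unpaired, minus the unconstrained MFE, clipped
at zero. Using MFE differences rather than ensemble free energies is a
documented deviation from partition-function accessibility scores,
consistent with the MFE-only engine; it preserves the invariants that
matter downstream (open cost ≥ 0, combined ≥ duplex). Seed match requires
≥6 consecutive Watson–Crick pairs within miRNA positions 2–8; scanning is
position-complete over all seed-matched windows, and the −20 kcal/mol
cutoff marks predictions. Coding sequence is treated exactly like 3′-UTR.

The bundled miR-2768-3p/ci pair is a **synthetic stand-in** (the real
sequences are study data not redistributed here): 22 nt, seed
fully Watson–Crick paired, one G:U wobble and exactly one unpairable base,
so the documented 21-of-22 pairing count is reproduced when wobble counts
as pairing (20/22 strict) — the wobble-counted mode is the recorded one.

## Synthetic data: what it emulates, and what it does not

The generator plants designed hairpins (22-nt mature, 8-nt loop, star arm
= reverse complement with 2 engineered mismatches kept central and ≥4 nt
apart) in an i.i.d.-uniform background genome. Two mismatches emulate the
imperfect mature/star duplex of real Drosha substrates; a perfect inverted
repeat would additionally be strand-ambiguous to any read-based method.
Designs are verified at construction against the structural criteria
(`true_energy_pass`), making planted-recovery experiments well-posed.
Libraries contain: mature reads (lengths 20–23, 5′ offsets in {−2..+2}
with configurable modal mass, default 0.95), star reads (binomial at
`star_fraction`, default 0.1 of mature depth), degradation fragments
(uniform 5′ starts over 150-nt windows, one strand), and contaminant reads
copied from a fixed 120-nt rRNA-like repeat unit that is also inserted
into the genome. Per-read provenance goes to a sidecar table, so precision
and recall reduce to joins. Reads are DNA on disk with constant 'I'
qualities; the filters are sequence-based.

Not emulated: sequencing errors and quality-dependent artifacts, realistic
transcriptome structure (degradation windows are genomic, not transcript
fragments), expression variation between miRNAs, and isomiR 3′ variation
beyond read-length sampling. Passing the recovery tests therefore shows
the filters separate the modelled read signatures at realistic depths; it
does not certify performance on libraries whose noise violates these
simplifications.

Study-scale defaults for the recovery experiments: 20 planted miRNAs at
mature depth 50, jitter modal mass 0.95, 100 degradation loci (depth 30),
50 contaminant insertions with 500 contaminant reads, on a 2×30-kb genome.
Under these conditions discovery achieves precision 1.0 with recall ≥0.9
(recall loss is almost always a hairpin whose star reads were binomially
unsampled), and ≥95% of degradation loci are rejected by the homogeneity
and arm-support filters.

## Numerical and degenerate-input conventions

Energies are reported to 0.1 kcal/mol. Coordinates are 0-based half-open
internally and 1-based closed in every written report (mappings TSV, GFF3,
sites TSV). Unpaired structures score 0.0; structures with zero pairs give
metrics {0, mature-span length, 0}. Read collapsing ranks ties
lexicographically; deduplication ties break to the lower start coordinate;
ambiguous reciprocal-best ties reject the pair. All simulation is driven
by explicit integer seeds and reruns are byte-identical, including the
pipeline summary (whose config hash excludes the output directory).

## Known limitations

- The bundled energy parameters are Turner-style, not an exact published
  table; absolute energies differ from ViennaRNA by a few kcal/mol on
  precursor-scale inputs (topology and threshold behaviour agree on
  designed hairpins, which tests check).
- The mapper ignores indels; for 18–24-nt reads at ≤1 mismatch this
  matches common small-RNA practice.
- Homology scores lack E-value calibration and the placement model has no
  probabilistic ancestral-state reconstruction; both are deliberate
  non-goals at this scale.
- miRDeep2's probabilistic log-odds scoring is intentionally replaced by
  the explicit filter cascade; the filters, not a composite score, are
  the decisive criteria.
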