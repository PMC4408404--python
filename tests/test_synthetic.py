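"""Generator guarantees: determinism, provenance, jitter and gain/loss truth."""

import random

import pytest

from lepimir import synthetic
from lepimir.discovery import MAX_MATURE_DEFECT, MIN_STEM_PAIRS
from lepimir.folding import fold, hairpin_metrics
from lepimir.phylo import assign_origin, parse_newick
from lepimir.synthetic import (ConfigError, GenerationError, PlantedMiRNA,
                               ReadSimConfig, design_precursor, make_genome,
                               simulate_gain_loss, simulate_reads)
from test_phylo import random_newick


def _planted(n, seed=11):
    rng = random.Random(seed)
    return [design_precursor(f"mir_{i:02d}", rng,
                             mature_arm=rng.choice(["five_prime", "three_prime"]))
            for i in range(n)]


class TestMakeGenome:
    def test_planting_records_truth(self):
        genome, truth = make_genome(1, 10000, _planted(2), rng_seed=7)
        mirnas = truth[truth["kind"] == "mirna"]
        assert len(mirnas) == 2
        spans = sorted(zip(mirnas["start"], mirnas["end"]))
        assert spans[0][1] <= spans[1][0]  # non-overlapping
        for _, row in mirnas.iterrows():
            assert row["end"] - row["start"] <= len(genome[row["contig"]])

    def test_planted_sequence_recoverable_from_genome(self):
        planted = _planted(3)
        genome, truth = make_genome(1, 10000, planted, rng_seed=3)
        from lepimir.mapping import revcomp

        for p in planted:
            contig, start, end, strand = p.genome_locus
            embedded = genome[contig][start:end]
            if strand == "-":
                embedded = revcomp(embedded)
            assert embedded == p.precursor_seq.replace("U", "T")

    def test_empty_planting_gives_background_only(self):
        genome, truth = make_genome(1, 5000, [], rng_seed=1)
        assert len(truth) == 0 and len(genome["contig_1"]) == 5000

    def test_same_seed_byte_identical(self, tmp_path):
        out = []
        for run in (1, 2):
            genome, _ = make_genome(2, 8000, _planted(4), contaminants=3,
                                    rng_seed=99)
            path = tmp_path / f"g{run}.fasta"
            synthetic.write_genome_fasta(genome, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_collision_exhaustion_names_contig(self):
        planted = _planted(2)
        # a genome barely larger than one precursor cannot host many copies
        with pytest.raises(GenerationError):
            make_genome(1, 600, planted * 1, contaminants=200, rng_seed=0)

    def test_duplicate_names_rejected(self):
        p = _planted(1) * 2
        with pytest.raises(GenerationError, match="unique"):
            make_genome(1, 10000, p, rng_seed=0)


class TestDesignByConstruction:
    def test_planted_precursors_pass_structural_criteria(self):
        """Designed hairpins clear the acceptance thresholds whenever
        true_energy_pass is set (design-by-construction invariant)."""
        for p in _planted(12, seed=5):
            if not p.true_energy_pass:
                continue
            st = fold(p.precursor_seq)
            m = hairpin_metrics(st, (p.mature_offset,
                                     p.mature_offset + len(p.mature_seq)))
            assert st.energy_kcal_mol < -18.0
            assert m["stem_pair_count"] >= MIN_STEM_PAIRS
            assert m["max_defect_in_mature"] <= MAX_MATURE_DEFECT
            assert m["n_hairpin_loops"] == 1

    def test_mature_is_substring_of_precursor(self):
        for p in _planted(6):
            assert p.mature_seq in p.precursor_seq


class TestSimulateReads:
    def test_provenance_accounts_for_every_read(self, small_library):
        prov = small_library["provenance"]
        assert len(prov) == len(small_library["reads"])
        counts = prov["source"].value_counts()
        assert counts.sum() == len(prov)
        assert set(counts.index) <= {"mature", "star", "degradation",
                                     "contaminant"}

    def test_modal_five_prime_share(self):
        planted = _planted(5)
        genome, truth = make_genome(1, 12000, planted, rng_seed=21)
        cfg = ReadSimConfig(mature_depth=200, star_fraction=0.0,
                            five_prime_jitter_modal_mass=0.95, rng_seed=22)
        reads, prov = simulate_reads(genome, truth, cfg)
        assert len(reads) == 5 * 200  # every planted locus at full depth
        mature = prov[prov.source == "mature"]
        assert mature.groupby("origin").size().eq(200).all()
        modal_share = (mature["offset"] == 0).mean()
        assert modal_share == pytest.approx(0.95, abs=0.03)

    def test_star_read_count_binomial(self):
        planted = _planted(1)
        genome, truth = make_genome(1, 5000, planted, rng_seed=31)
        totals = []
        for seed in range(20):
            cfg = ReadSimConfig(mature_depth=100, star_fraction=0.1,
                                rng_seed=seed)
            _, prov = simulate_reads(genome, truth, cfg)
            totals.append((prov["source"] == "star").sum())
        mean = sum(totals) / len(totals)
        se = (100 * 0.1 * 0.9 / 20) ** 0.5
        assert abs(mean - 10) <= 3 * se

    def test_only_mirna_sources_when_noise_disabled(self):
        planted = _planted(2)
        genome, truth = make_genome(1, 8000, planted, rng_seed=41)
        cfg = ReadSimConfig(mature_depth=30, degradation_loci=0,
                            contaminant_copies=0, rng_seed=42)
        _, prov = simulate_reads(genome, truth, cfg)
        assert set(prov["source"]) <= {"mature", "star"}
        assert set(prov[prov.source == "mature"]["origin"]) == \
            {p.name for p in planted}

    def test_invalid_star_fraction_rejected(self):
        with pytest.raises(ConfigError):
            ReadSimConfig(star_fraction=1.5)


class TestGainLoss:
    def test_no_loss_presence_equals_clade(self, rng):
        tree = parse_newick(random_newick(rng, 12))
        history, matrix = simulate_gain_loss(tree, 50, 0.0, rng_seed=8)
        for fam in history.families:
            birth = next(n for n in tree.preorder_node_iter()
                         if n.label == fam["birth_node"])
            clade = {l.taxon.label for l in birth.leaf_iter()}
            assert set(fam["present"]) == clade
            assert fam["lost"] == []

    def test_origin_always_birth_or_descendant_under_loss(self, rng):
        tree = parse_newick(random_newick(rng, 16))
        history, matrix = simulate_gain_loss(tree, 300, 0.15, rng_seed=9)
        nodes = {n.label: n for n in tree.preorder_node_iter()}
        for fam in history.families:
            origin = assign_origin(tree, matrix.loc[fam["name"]])
            birth = nodes[fam["birth_node"]]
            ancestors = set()
            n = origin
            while n is not None:
                ancestors.add(n.label)
                n = n.parent_node
            assert birth.label in ancestors  # origin is birth or a descendant

    def test_presence_rows_never_empty(self, rng):
        tree = parse_newick(random_newick(rng, 8))
        _, matrix = simulate_gain_loss(tree, 200, 0.4, rng_seed=10)
        assert ((matrix > 0).sum(axis=1) > 0).all()

    def test_unlengthed_tree_warns_and_uses_uniform(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.warns(UserWarning, match="branch lengths"):
            simulate_gain_loss(tree, 5, 0.0, rng_seed=2)

    def test_invalid_loss_prob(self, rng):
        tree = parse_newick(random_newick(rng, 4))
        with pytest.raises(ConfigError):
            simulate_gain_loss(tree, 5, 1.0, rng_seed=0)
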