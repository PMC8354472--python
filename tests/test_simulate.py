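"""Synthetic-data generators: gene families, IES histories, genomes, reads."""

import numpy as np
import pytest

from iesevo.catalog import insert_all
from iesevo.simulate import (GenomeConfig, MobileFamilyConfig, PresenceMatrix,
                             build_genome_pair, simulate_gene_families,
                             simulate_ies_history, simulate_reads)
from iesevo.trees import DUPLICATION, SPECIATION


def tree_topology_signature(tree):
    def sig(nid):
        node = tree.nodes[nid]
        if not node.children:
            return node.name
        return "(" + ",".join(sorted(sig(c) for c in node.children)) + ")"
    return sig(tree.root)


class TestGeneFamilies:
    def test_no_event_limit_reproduces_species_tree(self, species_tree):
        fams = simulate_gene_families(species_tree, 4, 0.0, 0.0, seed=1,
                                      with_sequences=False)
        want = tree_topology_signature(species_tree)
        for fam in fams:
            got = tree_topology_signature(fam.tree)
            # gene leaves are species names + suffix: strip the _gN part
            import re
            got = re.sub(r"_g\d+", "", got)
            assert got == want
            for nid in fam.tree.nodes:
                node = fam.tree.nodes[nid]
                if node.children:
                    assert node.event == SPECIATION

    def test_duplication_labels_and_species_tags(self, species_tree):
        fams = simulate_gene_families(species_tree, 30, 0.3, 0.0, seed=2,
                                      with_sequences=False)
        n_dup = 0
        for fam in fams:
            for nid in fam.tree.nodes:
                node = fam.tree.nodes[nid]
                if node.event == DUPLICATION:
                    n_dup += 1
                    assert node.species is not None
        assert n_dup > 0

    def test_fixed_seed_is_byte_identical(self, species_tree):
        a = simulate_gene_families(species_tree, 3, 0.2, 0.1, seed=9)
        b = simulate_gene_families(species_tree, 3, 0.2, 0.1, seed=9)
        for fa, fb in zip(a, b):
            assert fa.tree.to_newick(nhx=True) == fb.tree.to_newick(nhx=True)
            assert fa.cds == fb.cds

    def test_small_families_are_resimulated(self, species_tree):
        fams = simulate_gene_families(species_tree, 10, 0.0, 1.2, seed=3,
                                      with_sequences=False)
        assert all(len(f.tree.leaves()) >= 3 for f in fams)

    def test_negative_rates_rejected(self, species_tree):
        with pytest.raises(ValueError):
            simulate_gene_families(species_tree, 1, -0.1, 0.0, seed=0)

    def test_codon_alignment_translates_cleanly(self, species_tree):
        from Bio.Seq import Seq
        fams = simulate_gene_families(species_tree, 2, 0.0, 0.0, seed=5,
                                      n_codons=60)
        for fam in fams:
            for name, cds in fam.cds.items():
                assert "*" not in str(Seq(cds).translate())


class TestIesHistory:
    def test_zero_rates_no_root_gives_empty_matrix(self, species_tree):
        fams = simulate_gene_families(species_tree, 1, 0.0, 0.0, seed=1,
                                      with_sequences=False)
        matrix, hist = simulate_ies_history(fams[0].tree, 0.0, 0.0, 1.0,
                                            seed=2)
        assert matrix.n_loci == 0
        assert not hist.events

    def test_poisson_mean_of_gains_on_a_branch(self):
        # single-edge "tree": expected gains = rate * kb * branch length
        from iesevo.trees import Tree
        tree = Tree()
        root = tree.add_node(None, event=SPECIATION, species=0)
        tree.add_node(root, 0.5, "sp_g1", "leaf", 1)
        tree.add_node(root, 1e-9, "sp_g2", "leaf", 2)
        rate, kb, t = 2.0, 3.0, 0.5
        counts = []
        for rep in range(10_000):
            _, hist = simulate_ies_history(tree, rate, 0.0, kb, seed=rep)
            counts.append(hist.branch_counts[1]["gain"])
        mean = np.mean(counts)
        expected = rate * kb * t
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - expected) < 3 * se + 1e-9

    def test_infinite_loss_empties_all_tips(self, species_tree):
        fams = simulate_gene_families(species_tree, 1, 0.0, 0.0, seed=4,
                                      with_sequences=False)
        matrix, _ = simulate_ies_history(fams[0].tree, 1.0, 1e6, 1.0,
                                         seed=5, root_density_per_kb=10.0)
        assert matrix.n_loci == 0  # everything lost before any tip

    def test_event_tallies_match_counts(self, species_tree):
        fams = simulate_gene_families(species_tree, 5, 0.1, 0.0, seed=6,
                                      with_sequences=False)
        for i, fam in enumerate(fams):
            _, hist = simulate_ies_history(fam.tree, 1.0, 0.3, 1.0,
                                           seed=10 + i,
                                           root_density_per_kb=2.0)
            assert hist.tally_check()

    def test_events_consistent_with_endpoint_states(self, species_tree):
        fams = simulate_gene_families(species_tree, 3, 0.1, 0.0, seed=8,
                                      with_sequences=False)
        for i, fam in enumerate(fams):
            _, hist = simulate_ies_history(fam.tree, 1.0, 0.3, 1.0,
                                           seed=20 + i,
                                           root_density_per_kb=2.0)
            for loc, states in hist.node_states.items():
                for parent, child in fam.tree.branches():
                    n_ev = sum(1 for e in hist.events
                               if e["branch"] == child and e["locus"] == loc)
                    if states[parent] != states[child]:
                        assert n_ev % 2 == 1
                    else:
                        assert n_ev % 2 == 0

    def test_uncertain_masking_fraction(self, species_tree):
        fams = simulate_gene_families(species_tree, 1, 0.0, 0.0, seed=9,
                                      with_sequences=False)
        matrix, _ = simulate_ies_history(fams[0].tree, 2.0, 0.1, 5.0,
                                         seed=11, root_density_per_kb=5.0,
                                         uncertain_fraction=0.3)
        frac = np.mean(matrix.data == -1)
        assert 0.15 < frac < 0.45

    def test_presence_matrix_tsv_round_trip(self, species_tree, tmp_path):
        fams = simulate_gene_families(species_tree, 1, 0.0, 0.0, seed=9,
                                      with_sequences=False)
        matrix, _ = simulate_ies_history(fams[0].tree, 1.0, 0.1, 2.0,
                                         seed=12, root_density_per_kb=2.0,
                                         uncertain_fraction=0.1)
        path = tmp_path / "m.tsv"
        matrix.to_tsv(path)
        back = PresenceMatrix.from_tsv(path)
        assert back.tips == matrix.tips
        assert np.array_equal(back.data, matrix.data)


class TestGenomePair:
    def test_zero_density_means_mic_equals_mac(self):
        cfg = GenomeConfig(scaffold_length=5_000, ies_per_kb=0.0)
        pair = build_genome_pair(cfg, seed=1)
        assert pair.mic == pair.mac

    def test_round_trip_on_random_configs(self):
        rng = np.random.default_rng(0)
        for rep in range(50):
            cfg = GenomeConfig(
                n_scaffolds=int(rng.integers(1, 3)),
                scaffold_length=int(rng.integers(4_000, 9_000)),
                ies_per_kb=float(rng.uniform(0.1, 1.0)),
                floating_fraction=float(rng.uniform(0, 0.3)))
            pair = build_genome_pair(cfg, seed=rep)
            by_scaffold = {}
            for rec in pair.catalog:
                by_scaffold.setdefault(rec.scaffold, []).append(rec)
            for name in pair.mac:
                assert insert_all(pair.mac[name],
                                  by_scaffold.get(name, [])) == pair.mic[name]

    def test_requested_mobile_copies_all_in_catalog(self):
        fam = MobileFamilyConfig("FAM_T", length=233, n_copies=200,
                                 identity=0.72)
        cfg = GenomeConfig(scaffold_length=200_000, ies_per_kb=0.1,
                           mobile_families=(fam,))
        pair = build_genome_pair(cfg, seed=3)
        tagged = [r for r in pair.catalog
                  if r.meta.get("family") == "FAM_T"
                  and r.meta.get("role") == "mobile"]
        assert len(tagged) == 200
        assert all(r.length == 233 for r in tagged)

    def test_floating_engineering_verified_by_excision_equivalence(self):
        from iesevo.catalog import detect_floating
        cfg = GenomeConfig(scaffold_length=30_000, ies_per_kb=0.5,
                           floating_fraction=1.0)
        pair = build_genome_pair(cfg, seed=4)
        assert pair.catalog
        for rec in pair.catalog:
            offsets = detect_floating(pair.mic[rec.scaffold], rec,
                                      pair.mic_positions[rec.id])
            assert len(offsets) >= 2

    def test_excess_density_fails_loudly(self):
        cfg = GenomeConfig(scaffold_length=3_000, ies_per_kb=50.0)
        with pytest.raises(ValueError, match="usable TA sites"):
            build_genome_pair(cfg, seed=5)

    def test_ta_geometry_of_every_record(self):
        cfg = GenomeConfig(scaffold_length=20_000, ies_per_kb=0.8,
                           floating_fraction=0.2)
        pair = build_genome_pair(cfg, seed=6)
        for rec in pair.catalog:
            assert rec.excised_sequence.startswith("TA")
            mac = pair.mac[rec.scaffold]
            assert mac[rec.mac_position:rec.mac_position + 2] == "TA"


class TestReads:
    @pytest.fixture(scope="class")
    def pair(self):
        return build_genome_pair(
            GenomeConfig(scaffold_length=20_000, ies_per_kb=0.5), seed=7)

    def test_error_free_pure_mic_reads_are_substrings(self, pair):
        reads, _ = simulate_reads(pair, 2.0, 0.0, 0.0, 80, seed=1)
        mic = pair.mic
        names = reads.scaffold_names
        for i, seq in enumerate(reads.sequences()):
            if i >= 200:
                break
            assert seq in mic[names[reads.scaffold[i]]]

    def test_ies_read_fraction_matches_expectation(self, pair):
        f = 0.6
        reads, _ = simulate_reads(pair, 8.0, 0.0, f, 80, seed=2)
        ies_bp = sum(r.length for r in pair.catalog)
        mic_bp = sum(len(s) for s in pair.mic.values())
        # fraction of reads whose start lies inside an IES interior
        intervals = {}
        for rec in pair.catalog:
            intervals.setdefault(rec.scaffold, []).append(
                (pair.mic_positions[rec.id],
                 pair.mic_positions[rec.id] + rec.length))
        n_inside = 0
        n_mic = int((reads.origin == 0).sum())
        for i in range(len(reads)):
            if reads.origin[i] != 0:
                continue
            name = reads.scaffold_names[reads.scaffold[i]]
            s = reads.start[i]
            if any(lo <= s < hi for lo, hi in intervals.get(name, [])):
                n_inside += 1
        p = ies_bp / mic_bp
        se = np.sqrt(p * (1 - p) / n_mic)
        assert abs(n_inside / n_mic - p) < 4 * se

    def test_fixed_seed_identical_fastq(self, pair, tmp_path):
        r1, _ = simulate_reads(pair, 1.0, 0.01, 0.2, 60, seed=3)
        r2, _ = simulate_reads(pair, 1.0, 0.01, 0.2, 60, seed=3)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        r1.write_fastq(p1)
        r2.write_fastq(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_contamination_bounds_checked(self, pair):
        with pytest.raises(ValueError):
            simulate_reads(pair, 1.0, 0.0, 1.0, 60, seed=1)
        with pytest.raises(ValueError):
            simulate_reads(pair, -1.0, 0.0, 0.0, 60, seed=1)

    def test_irs_truth_mode_tracks_contamination(self, pair):
        _, irs = simulate_reads(pair, 20.0, 0.0, 0.5, 80, seed=4)
        vals = irs.irs.dropna()
        # MIC and MAC read depth roughly equal at f=0.5 on this genome
        assert 0.3 < vals.median() < 0.7
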