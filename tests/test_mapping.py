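"""Gene families, conserved blocks, alignment projection, co-orthologs."""

import numpy as np
import pytest

from iesevo.mapping import (MappedLocus, backtranslate, cluster_families,
                            conserved_blocks, cds_position_to_alignment_column,
                            find_conserved_ies, group_co_orthologs,
                            map_ies_to_alignment, mean_pairwise_identity,
                            pairwise_global_identity)


def union_find_oracle(edges, nodes):
    groups = {n: {n} for n in nodes}
    for a, b in edges:
        if groups[a] is not groups[b]:
            merged = groups[a] | groups[b]
            for n in merged:
                groups[n] = merged
    seen, out = set(), []
    for n in nodes:
        fs = frozenset(groups[n])
        if fs not in seen:
            seen.add(fs)
            out.append(set(fs))
    return out


class TestClusterFamilies:
    def test_transitive_closure(self):
        fams = cluster_families([("A", "B"), ("B", "C")])
        assert fams == [{"A", "B", "C"}]

    def test_pairs_below_min_members_dropped(self):
        assert cluster_families([("A", "B")]) == []

    def test_identity_filter(self):
        idents = {frozenset({"A", "B", "C"}): 0.4}
        assert cluster_families([("A", "B"), ("B", "C")],
                                identities=idents) == []

    def test_matches_union_find_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            nodes = [f"n{i}" for i in range(rng.integers(5, 25))]
            edges = [tuple(rng.choice(nodes, size=2, replace=False))
                     for _ in range(rng.integers(0, 30))]
            got = cluster_families(edges, min_members=1)
            want = [g for g in union_find_oracle(edges, nodes)
                    if any(n in {x for e in edges for x in e} for n in g)]
            assert sorted(map(sorted, got)) == sorted(map(sorted, want))


class TestBacktranslate:
    def test_gap_expands_to_triple_dash(self):
        prot = {"x": "M-A", "y": "MKA"}
        cds = {"x": "ATGGCT", "y": "ATGAAAGCT"}
        out = backtranslate(prot, cds)
        assert out["x"] == "ATG---GCT"
        assert out["y"] == "ATGAAAGCT"

    def test_ungapped_is_concatenated_codons(self):
        out = backtranslate({"x": "MK"}, {"x": "ATGAAA"})
        assert out["x"] == "ATGAAA"

    def test_length_mismatch_excludes_gene(self):
        out = backtranslate({"x": "MK", "y": "MK"},
                            {"x": "ATGAAA", "y": "ATGAA"})
        assert set(out) == {"x"}

    def test_degapping_recovers_cds_on_random_families(self, species_tree):
        from iesevo.simulate import simulate_gene_families
        fams = simulate_gene_families(species_tree, 3, 0.1, 0.0, seed=2,
                                      n_codons=40)
        for fam in fams:
            out = backtranslate(fam.protein_alignment, fam.cds)
            for name, row in out.items():
                assert row.replace("-", "") == fam.cds[name]


class TestConservedBlocks:
    def test_identical_sequences_keep_everything(self):
        aln = {"a": "MKLV" * 5, "b": "MKLV" * 5, "c": "MKLV" * 5}
        assert conserved_blocks(aln).all()

    def test_gappy_column_breaks_blocks(self):
        base = "MKLVMKLVMKLV"  # 12 columns
        a = base[:6] + "-" + base[7:]
        b = base[:6] + "-" + base[7:]
        aln = {"a": a, "b": b, "c": base, "d": base}
        mask = conserved_blocks(aln, min_block=3)
        assert not mask[6]

    def test_mask_agrees_with_per_column_oracle(self):
        rng = np.random.default_rng(1)
        letters = list("ACDEFGHIKLMNPQRSTVWY-")
        n_col, n_seq = 60, 6
        aln = {f"s{i}": "".join(rng.choice(letters, size=n_col))
               for i in range(n_seq)}
        mask = conserved_blocks(aln, min_block=4, max_gap_fraction=0.2,
                                min_column_identity=0.5)
        good = []
        for c in range(n_col):
            col = [aln[f"s{i}"][c] for i in range(n_seq)]
            gaps = col.count("-")
            res = [x for x in col if x != "-"]
            ok = gaps / n_seq <= 0.2 and res and \
                max(res.count(r) for r in set(res)) / len(res) >= 0.5
            good.append(ok)
        expect = np.zeros(n_col, dtype=bool)
        run = 0
        for c in range(n_col + 1):
            if c < n_col and good[c]:
                run += 1
            else:
                if run >= 4:
                    expect[c - run:c] = True
                run = 0
        assert np.array_equal(mask, expect)


class TestProjection:
    class FakeIes:
        def __init__(self, pos, offsets=(0,)):
            self.id = "i1"
            self.mac_position = pos
            self.floating_offsets = list(offsets)
            self.species = "sp"

    def test_ungapped_alignment_columns(self):
        row = "ATGAAATTAGGG"
        locus = map_ies_to_alignment(
            self.FakeIes(110), "g1", {"g1": row},
            lambda p: p - 100 if 100 <= p < 112 else None)
        assert locus.intervals == [(10, 12)]

    def test_gap_between_t_and_a_spans_gap_columns(self):
        row = "ATGT--AGGG"
        # CDS indices: A0 T1 G2 T3 A4 ...: the TA at CDS 3-4 spans cols 3..6
        locus = map_ies_to_alignment(
            self.FakeIes(103), "g1", {"g1": row},
            lambda p: p - 100)
        assert locus.intervals == [(3, 7)]

    def test_noncoding_position_unmappable(self):
        locus = map_ies_to_alignment(
            self.FakeIes(50), "g1", {"g1": "ATG"}, lambda p: None)
        assert locus is None

    def test_column_lookup_bounds(self):
        with pytest.raises(IndexError):
            cds_position_to_alignment_column("AT-", 2)


class TestGrouping:
    def _locus(self, iid, intervals, family="f1"):
        return MappedLocus(iid, family, f"gene_{iid}", "sp", intervals)

    def test_identical_columns_form_one_group(self):
        mask = np.ones(20, dtype=bool)
        groups = group_co_orthologs(
            [self._locus("a", [(5, 7)]), self._locus("b", [(5, 7)])], mask)
        assert len(groups) == 1 and len(groups[0]) == 2

    def test_off_block_floating_alternative_discards_group(self):
        mask = np.ones(20, dtype=bool)
        mask[15:] = False
        groups = group_co_orthologs(
            [self._locus("a", [(5, 7)]),
             self._locus("b", [(5, 7), (16, 18)])], mask)
        assert groups == []

    def test_matches_brute_force_pairwise_closure(self):
        rng = np.random.default_rng(2)
        mask = np.ones(50, dtype=bool)
        loci = []
        for i in range(60):
            start = int(rng.integers(0, 48))
            loci.append(self._locus(f"l{i}", [(start, start + 2)]))
        groups = group_co_orthologs(loci, mask)
        cols = {m.ies_id: set(range(*m.intervals[0])) for m in loci}
        edges = [(a, b) for a in cols for b in cols
                 if a < b and cols[a] & cols[b]]
        oracle = union_find_oracle(edges, list(cols))
        got = sorted(sorted(m.ies_id for m in g) for g in groups)
        want = sorted(sorted(g) for g in oracle)
        assert got == want

    def test_each_ies_in_at_most_one_group(self):
        rng = np.random.default_rng(3)
        mask = np.ones(30, dtype=bool)
        loci = []
        for i in range(40):
            s = int(rng.integers(0, 28))
            loci.append(self._locus(f"l{i}", [(s, s + 2)]))
        groups = group_co_orthologs(loci, mask)
        ids = [m.ies_id for g in groups for m in g]
        assert len(ids) == len(set(ids))


class TestConservedIes:
    def _groups_one(self, ids):
        return [[MappedLocus(i, "f1", f"g_{i}", None, [(0, 2)])
                 for i in ids]]

    def test_identical_sequences_across_five_species(self):
        ids = [f"i{k}" for k in range(5)]
        seqs = {i: "TAGGGCATTTAAACCGGTTAA" for i in ids}
        species_of = {f"i{k}": f"sp{k}" for k in range(5)}
        subclades = {"sp0": "A", "sp1": "A", "sp2": "A", "sp3": "B",
                     "sp4": "B"}
        out = find_conserved_ies(self._groups_one(ids), seqs, species_of,
                                 subclades)
        assert len(out) == 1
        assert out[0]["best_cross_identity"] == pytest.approx(1.0)

    def test_four_species_not_reported(self):
        ids = [f"i{k}" for k in range(4)]
        seqs = {i: "TAGGGCATTTAAACCGGTTAA" for i in ids}
        species_of = {f"i{k}": f"sp{k}" for k in range(4)}
        subclades = {"sp0": "A", "sp1": "A", "sp2": "B", "sp3": "B"}
        assert find_conserved_ies(self._groups_one(ids), seqs, species_of,
                                  subclades) == []

    def test_single_subclade_not_eligible(self):
        ids = [f"i{k}" for k in range(5)]
        seqs = {i: "TAGGGCATTTAAACCGGTTAA" for i in ids}
        species_of = {f"i{k}": f"sp{k}" for k in range(5)}
        subclades = {f"sp{k}": "A" for k in range(5)}
        assert find_conserved_ies(self._groups_one(ids), seqs, species_of,
                                  subclades) == []

    def test_identity_matches_independent_aligner(self):
        from Bio import Align
        a, b = "TATTTGGCCAATTAGCAATT", "TATTTGGCCTATTAGCATT"
        ours = pairwise_global_identity(a, b)
        al = Align.PairwiseAligner(mode="global", match_score=1,
                                   mismatch_score=-1, open_gap_score=-2,
                                   extend_gap_score=-0.5)
        aln = al.align(a, b)[0]
        sa, sb = str(aln[0]), str(aln[1])
        matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
        assert ours == pytest.approx(matches / len(sa))

    def test_mean_pairwise_identity_counts_gaps(self):
        aln = {"a": "MK-V", "b": "MKLV"}
        assert mean_pairwise_identity(aln) == pytest.approx(3 / 4)
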