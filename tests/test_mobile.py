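"""Mobile-IES discovery: similarity, boundary/flank rules, clustering,
profiles and scanning."""

import numpy as np
import pytest

from iesevo.mobile import (SimilarityHit, all_vs_all, boundary_rule,
                           build_profile, cluster_candidates,
                           dinucleotide_shuffle, locus_class, revcomp,
                           scan_profiles, summarize)


def make_hit(q_iv, s_iv, query="q", subject="s"):
    return SimilarityHit(query, subject, q_iv, s_iv, 90.0,
                         max(q_iv[1] - q_iv[0], s_iv[1] - s_iv[0]),
                         100.0, 1e-20)


def random_at_rich(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n,
                              p=[0.4, 0.1, 0.1, 0.4]))


class TestAllVsAll:
    def test_identical_sequences_hit_full_length(self):
        rng = np.random.default_rng(0)
        seq = "TA" + random_at_rich(rng, 198)
        decoys = {f"d{i}": random_at_rich(rng, 200) for i in range(20)}
        seqs = {"a": seq, "b": seq, **decoys}
        hits = all_vs_all(seqs, max_evalue=1e-8, seed=1)
        pair = [h for h in hits if {h.query, h.subject} == {"a", "b"}]
        assert len(pair) == 1
        h = pair[0]
        assert h.identity == pytest.approx(100.0)
        assert h.query_interval == (0, 200)
        assert h.subject_interval == (0, 200)

    def test_reverse_complement_detected(self):
        rng = np.random.default_rng(1)
        seq = "TA" + random_at_rich(rng, 198)
        seqs = {"a": seq, "b": revcomp(seq),
                **{f"d{i}": random_at_rich(rng, 200) for i in range(20)}}
        hits = all_vs_all(seqs, max_evalue=1e-8, seed=1)
        pair = [h for h in hits if {h.query, h.subject} == {"a", "b"}]
        assert pair and pair[0].strand == "-"

    def test_unrelated_at_rich_pairs_rarely_pass(self):
        rng = np.random.default_rng(2)
        seqs = {f"r{i}": random_at_rich(rng, 200) for i in range(50)}
        hits = all_vs_all(seqs, max_evalue=1e-8, seed=3)
        n_pairs = 50 * 49 / 2
        assert len(hits) / n_pairs < 0.01

    def test_short_sequences_excluded(self):
        hits = all_vs_all({"a": "TAGGTT", "b": "TAGGTT"}, seed=1)
        assert hits == []


class TestBoundaryRule:
    def test_full_length_alignment_passes(self):
        assert boundary_rule(make_hit((0, 60), (0, 60)), 60, 60)

    def test_missing_last_20nt_fails(self):
        assert not boundary_rule(make_hit((0, 50), (0, 60)), 60, 60)

    def test_missing_start_fails(self):
        assert not boundary_rule(make_hit((5, 60), (0, 60)), 60, 60)

    def test_short_sequence_needs_full_coverage(self):
        assert boundary_rule(make_hit((0, 30), (0, 30)), 30, 30)
        assert not boundary_rule(make_hit((0, 29), (0, 30)), 30, 30)

    def test_brute_force_interval_check_agrees(self):
        rng = np.random.default_rng(4)
        for _ in range(500):
            qlen, slen = rng.integers(25, 300, size=2)
            q = tuple(sorted(rng.integers(0, qlen + 1, size=2)))
            s = tuple(sorted(rng.integers(0, slen + 1, size=2)))
            hit = make_hit(q, s)
            margin = 20
            def covers(iv, n):
                want = set(range(0, min(margin, n))) | \
                    set(range(max(n - margin, 0), n))
                return want <= set(range(iv[0], iv[1]))
            assert boundary_rule(hit, qlen, slen) == \
                (covers(q, qlen) and covers(s, slen))


class TestLocusClass:
    def test_identical_flanks_are_homologous_locus(self):
        rng = np.random.default_rng(5)
        flank = random_at_rich(rng, 200)
        out = locus_class(make_hit((0, 60), (0, 60)), flank, flank)
        assert out["class"] == "homologous_locus"

    def test_unrelated_flanks_are_candidate_mobile(self):
        rng = np.random.default_rng(6)
        out = locus_class(make_hit((0, 60), (0, 60)),
                          random_at_rich(rng, 200),
                          random_at_rich(rng, 200))
        assert out["class"] == "candidate_mobile"

    def test_missing_flank_flagged_partial(self):
        rng = np.random.default_rng(7)
        out = locus_class(make_hit((0, 60), (0, 60)), None,
                          random_at_rich(rng, 200))
        assert out["partial"]


class TestClustering:
    def test_chain_forms_single_family(self):
        fams = cluster_candidates([("a", "b"), ("b", "c")])
        assert fams[0]["members"] == ["a", "b", "c"]

    def test_nine_member_cluster_not_profiled(self):
        pairs = [(f"m{i}", f"m{i+1}") for i in range(8)]  # 9 members
        fams = cluster_candidates(pairs)
        assert len(fams[0]["members"]) == 9
        assert not fams[0]["profiled"]
        pairs10 = [(f"m{i}", f"m{i+1}") for i in range(9)]
        assert cluster_candidates(pairs10)[0]["profiled"]

    def test_matches_union_find_oracle(self):
        from test_mapping import union_find_oracle
        rng = np.random.default_rng(8)
        nodes = [f"n{i}" for i in range(30)]
        pairs = [tuple(rng.choice(nodes, 2, replace=False))
                 for _ in range(25)]
        fams = cluster_candidates(pairs)
        touched = {x for p in pairs for x in p}
        oracle = [g for g in union_find_oracle(pairs, nodes)
                  if g & touched]
        assert sorted(sorted(f["members"]) for f in fams) == \
            sorted(sorted(g) for g in oracle)


class TestProfiles:
    def test_identical_members_give_that_consensus(self):
        rng = np.random.default_rng(9)
        seq = "TA" + random_at_rich(rng, 98)
        fam = build_profile({f"m{i}": seq for i in range(10)})
        assert fam.consensus == seq
        # every consensus column is the most informative residue
        codes = {"A": 0, "C": 1, "G": 2, "T": 3}
        for i, base in enumerate(seq):
            assert fam.profile[i].argmax() == codes[base]

    def test_at_rich_consensus_flagged_suspect(self):
        seq = "TA" + "AT" * 60
        fam = build_profile({f"m{i}": seq for i in range(10)})
        assert fam.composition_suspect

    def test_requires_two_members(self):
        with pytest.raises(ValueError):
            build_profile({"only": "TAGG" * 20})

    def test_profile_redetects_its_seeds(self):
        from iesevo.simulate import MobileFamilyConfig, family_copy, \
            make_family_consensus
        rng = np.random.default_rng(10)
        cfg = MobileFamilyConfig("F", length=120, identity=0.70)
        consensus = make_family_consensus(rng, cfg)
        members = {f"m{i}": family_copy(rng, consensus, cfg)
                   for i in range(10)}
        decoys = {f"d{i}": random_at_rich(rng, 120) for i in range(60)}
        fam = build_profile(members, family_id="F")
        hits = scan_profiles([fam], {**members, **decoys}, seed=11)
        found = {h["ies_id"] for h in hits}
        assert set(members) <= found


class TestScanClassification:
    @pytest.fixture(scope="class")
    def family_and_catalog(self):
        rng = np.random.default_rng(12)
        core = "TA" + random_at_rich(rng, 118)
        members = {f"m{i}": core for i in range(10)}
        fam = build_profile(members, family_id="FAM_X")
        catalog = dict(members)
        # nested: the element inside a longer IES, away from extremities
        catalog["nested1"] = "TA" + random_at_rich(rng, 10) + core + \
            random_at_rich(rng, 12)
        # mobile with 2 bp of boundary slack
        catalog["slack1"] = "TA" + core[4:]
        for i in range(40):
            catalog[f"bg{i}"] = random_at_rich(rng, 130)
        return fam, catalog

    def test_partition_into_mobile_and_nested(self, family_and_catalog):
        fam, catalog = family_and_catalog
        hits = scan_profiles([fam], catalog, seed=13)
        calls = {h["ies_id"]: h["class"] for h in hits}
        assert all(calls[f"m{i}"] == "mobile" for i in range(10))
        assert calls["nested1"] == "nested"
        assert calls["slack1"] == "mobile"  # within the 3 bp tolerance
        assert all(h["class"] in ("mobile", "nested") for h in hits)

    def test_shuffled_decoys_yield_no_hits(self, family_and_catalog):
        fam, catalog = family_and_catalog
        rng = np.random.default_rng(14)
        decoys = {k: dinucleotide_shuffle(v, rng)
                  for k, v in catalog.items()}
        hits = scan_profiles([fam], decoys, seed=15)
        assert hits == []


class TestShuffle:
    def test_preserves_dinucleotide_composition(self):
        rng = np.random.default_rng(16)
        seq = random_at_rich(rng, 300)
        shuf = dinucleotide_shuffle(seq, rng)
        def dinucs(s):
            out = {}
            for a, b in zip(s[:-1], s[1:]):
                out[a + b] = out.get(a + b, 0) + 1
            return out
        assert sorted(shuf) == sorted(seq)
        assert dinucs(shuf) == dinucs(seq)


class TestSummary:
    def test_totals_and_retention_rule(self):
        rng = np.random.default_rng(17)
        core = "TA" + random_at_rich(rng, 118)
        fam = build_profile({f"m{i}": core for i in range(10)},
                            family_id="FAM_1")
        hits = ([{"family": "FAM_1", "ies_id": f"a{i}", "class": "mobile"}
                 for i in range(12)]
                + [{"family": "FAM_1", "ies_id": f"b{i}", "class": "nested"}
                   for i in range(3)]
                + [{"family": "FAM_1", "ies_id": f"c{i}", "class": "mobile"}
                   for i in range(4)])
        species = {f"a{i}": "pson" for i in range(12)}
        species.update({f"b{i}": "pson" for i in range(3)})
        species.update({f"c{i}": "ptre" for i in range(4)})
        tab = summarize([fam], hits, species)
        row = tab[tab.family == "FAM_1"].iloc[0]
        assert row.pson_mobile == 12 and row.pson_nested == 3
        assert row.ptre_mobile == 4
        total = tab[tab.family == "TOTAL"].iloc[0]
        assert total.pson_mobile == 12 and total.ptre_mobile == 4

    def test_family_below_ten_mobile_everywhere_excluded(self):
        rng = np.random.default_rng(18)
        core = "TA" + random_at_rich(rng, 118)
        fam = build_profile({f"m{i}": core for i in range(10)},
                            family_id="FAM_2")
        hits = [{"family": "FAM_2", "ies_id": f"a{i}", "class": "mobile"}
                for i in range(9)]
        species = {f"a{i}": "pson" for i in range(9)}
        assert summarize([fam], hits, species).empty
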