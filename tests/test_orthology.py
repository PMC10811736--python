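import numpy as np
import pytest

from aoapan.align import local_align
from aoapan.orthology import (
    OrthoHit,
    ProteinEntry,
    all_vs_all_hits,
    build_presence_matrix,
    cluster_orthogroups,
    filter_ortho_hits,
    orthogroup_table,
)
from aoapan.synthetic import AA_ALPHABET, random_sequence

from _oracles import sw_score_oracle, transitive_closure_oracle


def _hit(q, s, ident=90.0, qcov=0.9, scov=0.9):
    return OrthoHit(q, s, ident, 100, qcov, scov, 100.0)


def _random_protein(rng, n=80):
    return random_sequence(n, rng, AA_ALPHABET)


class TestAllVsAllHits:
    def test_identical_proteins_full_identity(self, rng):
        seq = _random_protein(rng, 100)
        prots = [ProteinEntry("p1", "g1", seq), ProteinEntry("p2", "g2", seq)]
        (h,) = all_vs_all_hits(prots)
        assert h.percent_identity == 100.0
        assert h.query_coverage == 1.0 and h.subject_coverage == 1.0

    def test_prefilter_suppresses_unshared_pairs(self):
        # disjoint alphabets share no 4-mer
        prots = [
            ProteinEntry("p1", "g1", "ACDEF" * 10),
            ProteinEntry("p2", "g2", "GHIKL" * 10),
        ]
        assert all_vs_all_hits(prots) == []

    def test_embedded_repeat_matches_dp_oracle(self, rng):
        repeat = _random_protein(rng, 60)
        a = _random_protein(rng, 30) + repeat + _random_protein(rng, 30)
        b = _random_protein(rng, 30) + repeat + _random_protein(rng, 30)
        prots = [ProteinEntry("pa", "g1", a), ProteinEntry("pb", "g2", b)]
        (h,) = all_vs_all_hits(prots, min_kmer_shared=0)
        assert h.alignment_length >= 60
        assert h.query_coverage >= 0.5 and h.subject_coverage >= 0.5
        assert h.score == sw_score_oracle(a, b, protein=True)

    def test_optimal_score_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(10):
            a = _random_protein(rng, int(rng.integers(20, 60)))
            b = _random_protein(rng, int(rng.integers(20, 60)))
            aln = local_align(a, b, protein=True)
            expected = sw_score_oracle(a, b, protein=True)
            got = aln.score if aln is not None else 0.0
            assert got == expected

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            all_vs_all_hits(
                [ProteinEntry("p1", "g1", ""), ProteinEntry("p2", "g1", "ACD")]
            )


class TestFilterOrthoHits:
    def test_identity_just_below_threshold_removed(self):
        assert filter_ortho_hits([_hit("a", "b", ident=49.9)]) == []

    def test_inclusive_boundaries_kept(self):
        h = _hit("a", "b", ident=50.0, qcov=0.5, scov=0.5)
        assert filter_ortho_hits([h]) == [h]

    def test_coverage_enforced_on_both_sides(self):
        assert filter_ortho_hits([_hit("a", "b", ident=90.0, qcov=0.4)]) == []
        assert filter_ortho_hits([_hit("a", "b", ident=90.0, scov=0.4)]) == []


class TestClusterOrthogroups:
    def _proteins(self, ids):
        return [ProteinEntry(i, f"g_{i}", "ACDEFGHIKL") for i in ids]

    def test_chained_edges_and_isolated_node(self):
        prots = self._proteins(["p1", "p2", "p3", "p4"])
        hits = [_hit("p1", "p2"), _hit("p2", "p3")]
        ogs = cluster_orthogroups(hits, prots)
        assert {og.members for og in ogs} == {
            frozenset({"p1", "p2", "p3"}),
            frozenset({"p4"}),
        }

    def test_no_edges_gives_all_singletons(self):
        prots = self._proteins(["p1", "p2", "p3"])
        ogs = cluster_orthogroups([], prots)
        assert all(len(og) == 1 for og in ogs)

    def test_unknown_protein_in_hit_is_error(self):
        with pytest.raises(ValueError, match="unknown protein"):
            cluster_orthogroups([_hit("p1", "zz")], self._proteins(["p1", "p2"]))

    def test_partition_property(self, planted_collection):
        pg = planted_collection
        prots = [
            ProteinEntry(p.id, g, p.sequence)
            for g, ps in pg.proteomes.items()
            for p in ps
        ]
        hits = filter_ortho_hits(all_vs_all_hits(prots))
        ogs = cluster_orthogroups(hits, prots)
        members = [m for og in ogs for m in og.members]
        assert len(members) == len(prots)
        assert len(set(members)) == len(members)

    def test_planted_families_recovered_exactly(self, planted_collection):
        pg = planted_collection
        prots = [
            ProteinEntry(p.id, g, p.sequence)
            for g, ps in pg.proteomes.items()
            for p in ps
        ]
        hits = filter_ortho_hits(all_vs_all_hits(prots))
        ogs = cluster_orthogroups(hits, prots)
        truth = {
            frozenset(genes)
            for genes in pg.truth.family_members().values()
        }
        assert {og.members for og in ogs} == truth

    def test_matches_transitive_closure_oracle(self, rng):
        for trial in range(5):
            ids = [f"p{i}" for i in range(int(rng.integers(5, 50)))]
            n_edges = int(rng.integers(0, 2 * len(ids)))
            edges = [
                tuple(rng.choice(ids, 2, replace=False)) for _ in range(n_edges)
            ]
            ogs = cluster_orthogroups(
                [_hit(a, b) for a, b in edges], self._proteins(ids)
            )
            assert {og.members for og in ogs} == transitive_closure_oracle(ids, edges)

    def test_raising_identity_threshold_only_splits_components(self, planted_collection):
        pg = planted_collection
        prots = [
            ProteinEntry(p.id, g, p.sequence)
            for g, ps in pg.proteomes.items()
            for p in ps
        ]
        hits = all_vs_all_hits(prots)
        loose = cluster_orthogroups(filter_ortho_hits(hits, min_identity=40), prots)
        strict = cluster_orthogroups(filter_ortho_hits(hits, min_identity=60), prots)
        for og in strict:
            assert any(og.members <= big.members for big in loose)


class TestPresenceMatrix:
    def _og(self, og_id, members):
        from aoapan.orthology import Orthogroup

        return Orthogroup(
            og_id=og_id,
            members=frozenset(members),
            genomes=frozenset(m.split("@")[1] for m in members),
        )

    def test_row_for_two_of_three_genomes(self):
        og = self._og("OG00001", ["p1@g1", "p2@g2"])
        m = build_presence_matrix([og], ["g1", "g2", "g3"])
        assert m.loc["OG00001"].tolist() == [1, 1, 0]

    def test_singleton_row_sum(self):
        og = self._og("OG00001", ["p1@g2"])
        m = build_presence_matrix([og], ["g1", "g2"])
        assert m.loc["OG00001"].sum() == 1

    def test_cell_count_conservation(self, planted_collection):
        pg = planted_collection
        prots = [
            ProteinEntry(p.id, g, p.sequence)
            for g, ps in pg.proteomes.items()
            for p in ps
        ]
        ogs = cluster_orthogroups([], prots)
        m = build_presence_matrix(ogs, list(pg.genomes))
        assert m.to_numpy().sum() == sum(len(og.genomes) for og in ogs)

    def test_unknown_genome_is_error(self):
        og = self._og("OG00001", ["p1@gX"])
        with pytest.raises(ValueError, match="unknown genome"):
            build_presence_matrix([og], ["g1"])

    def test_membership_table_shape(self, planted_collection):
        pg = planted_collection
        prots = [
            ProteinEntry(p.id, g, p.sequence)
            for g, ps in pg.proteomes.items()
            for p in ps
        ]
        ogs = cluster_orthogroups([], prots)
        table = orthogroup_table(ogs, prots)
        assert set(table.columns) == {"og_id", "gene_id", "genome_id"}
        assert len(table) == len(prots)
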