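"""Ortholog-clustering stage: MGE exclusion, alignment engine, BBBH, clusters."""

import itertools
from collections import Counter

import numpy as np
import pytest

from pancore import (
    ClusteringParams,
    GeneRecord,
    PanSimConfig,
    ProteinAligner,
    SimilarityHit,
    all_vs_all_hits,
    best_bidirectional_hits,
    cluster_orthologs,
    exclude_mges,
    read_similarity_table,
    simulate_proteomes,
    write_similarity_table,
)
from pancore.cluster import strain_map, validate_imported_hits

PARAMS = ClusteringParams()


def _records(strain, sequences, product="hypothetical protein"):
    return [GeneRecord(f"g{i}", strain, product, s) for i, s in enumerate(sequences)]


def _random_protein(rng, n=100):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestExcludeMges:
    def test_keyword_match_removes_and_flags(self):
        records = [
            GeneRecord("g1", "A", "hypothetical protein", "MKV"),
            GeneRecord("g2", "A", "IS21 family transposase", "MAA"),
        ]
        kept = exclude_mges(records, PARAMS)
        assert [r.gene_id for r in kept] == ["g1"]
        assert records[1].is_mge and not records[0].is_mge

    def test_empty_keyword_list_is_identity(self):
        records = _records("A", ["MKV", "MAA"], product="phage integrase")
        kept = exclude_mges(records, ClusteringParams(mge_keywords=()))
        assert kept == records

    def test_all_mge_input_yields_empty_output(self):
        records = _records("A", ["MKV", "MAA"], product="phage tail protein")
        assert exclude_mges(records, PARAMS) == []

    def test_matching_is_case_insensitive(self):
        records = _records("A", ["MKV"], product="Putative TRANSPOSASE")
        assert exclude_mges(records, PARAMS) == []


class TestProteinAligner:
    def test_identical_proteins_align_full_length_at_full_identity(self):
        rng = np.random.default_rng(0)
        seq = _random_protein(rng)
        a = GeneRecord("g1", "A", "p", seq)
        b = GeneRecord("g2", "B", "p", seq)
        hit = ProteinAligner().align(a, b)
        assert hit.pct_identity == 100.0
        assert hit.align_length == 100
        assert hit.e_value < 1e-30

    def test_unrelated_proteins_rarely_reach_significance(self):
        """Null behavior of the Karlin-Altschul E-value: random 100-mers
        essentially never score E <= 1e-5."""
        aligner = ProteinAligner(prescreen_k=1)  # disable the word filter
        significant = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = GeneRecord("g1", "A", "p", _random_protein(rng))
            b = GeneRecord("g2", "B", "p", _random_protein(rng))
            hit = aligner.align(a, b)
            if hit is not None and hit.e_value <= PARAMS.bbbh_e_max:
                significant += 1
        assert significant <= 1

    def test_search_prescreen_skips_wordless_pairs(self):
        rng = np.random.default_rng(1)
        shared = _random_protein(rng)
        queries = [GeneRecord("q1", "A", "p", shared)]
        subjects = [
            GeneRecord("s1", "B", "p", shared),
            GeneRecord("s2", "B", "p", _random_protein(rng)),
        ]
        hits = ProteinAligner().search(queries, subjects)
        assert {h.subject_id for h in hits} <= {"B|s1", "B|s2"}
        assert "B|s1" in {h.subject_id for h in hits}


class TestBestBidirectionalHits:
    SMAP = {"A|a": "A", "B|b": "B", "B|c": "B"}

    def _hit(self, q, s, bit=300.0, ident=97.0, e=1e-50):
        return SimilarityHit(q, s, ident, 200, e, bit)

    def test_symmetric_reciprocal_pair_is_kept(self):
        hits = [self._hit("A|a", "B|b"), self._hit("B|b", "A|a")]
        assert best_bidirectional_hits(hits, PARAMS, self.SMAP) == {
            frozenset({"A|a", "B|b"})
        }

    def test_identity_just_below_cutoff_is_excluded(self):
        hits = [self._hit("A|a", "B|b", ident=49.9), self._hit("B|b", "A|a", ident=49.9)]
        assert best_bidirectional_hits(hits, PARAMS, self.SMAP) == set()

    def test_identity_at_cutoff_is_kept(self):
        hits = [self._hit("A|a", "B|b", ident=50.0), self._hit("B|b", "A|a", ident=50.0)]
        assert best_bidirectional_hits(hits, PARAMS, self.SMAP) == {
            frozenset({"A|a", "B|b"})
        }

    def test_non_reciprocal_best_is_excluded(self):
        # a's best is b, but b's best is c
        smap = {"A|a": "A", "A|c": "A", "B|b": "B"}
        hits = [
            self._hit("A|a", "B|b", bit=300),
            self._hit("B|b", "A|a", bit=300),
            self._hit("B|b", "A|c", bit=400),
            self._hit("A|c", "B|b", bit=400),
        ]
        assert best_bidirectional_hits(hits, PARAMS, smap) == {
            frozenset({"A|c", "B|b"})
        }

    def test_e_value_cutoff_applies_to_both_directions(self):
        hits = [self._hit("A|a", "B|b"), self._hit("B|b", "A|a", e=1e-3)]
        assert best_bidirectional_hits(hits, PARAMS, self.SMAP) == set()

    def test_bit_score_ties_break_deterministically(self):
        smap = {"A|a": "A", "B|b1": "B", "B|b2": "B"}
        hits = [
            self._hit("A|a", "B|b2"), self._hit("A|a", "B|b1"),
            self._hit("B|b1", "A|a"), self._hit("B|b2", "A|a"),
        ]
        # both subjects tie on (bit, identity); the smaller id must win
        assert best_bidirectional_hits(hits, PARAMS, smap) == {
            frozenset({"A|a", "B|b1"})
        }


class TestClusterOrthologs:
    def test_five_strain_clique_forms_one_cluster(self):
        strains = "ABCDE"
        proteomes = {s: [GeneRecord("g", s, "p", "M" * 100)] for s in strains}
        hits = []
        for s1, s2 in itertools.permutations(strains, 2):
            hits.append(SimilarityHit(f"{s1}|g", f"{s2}|g", 90.0, 200, 1e-60, 350.0))
        pairs = best_bidirectional_hits(hits, PARAMS, strain_map(proteomes))
        assert len(pairs) == 10
        clusters = cluster_orthologs(pairs, hits, PARAMS, proteomes)
        assert len(clusters) == 1 and clusters[0].size == 5

    def test_gene_without_edges_becomes_singleton(self):
        proteomes = {
            "A": [GeneRecord("g", "A", "p", "M" * 100)],
            "B": [GeneRecord("g", "B", "p", "W" * 100)],
        }
        clusters = cluster_orthologs(set(), [], PARAMS, proteomes)
        assert len(clusters) == 2
        assert all(c.size == 1 for c in clusters)

    def test_edges_below_cluster_thresholds_are_dropped(self):
        proteomes = {
            "A": [GeneRecord("g", "A", "p", "M" * 100)],
            "B": [GeneRecord("g", "B", "p", "M" * 100)],
        }
        # passes BBBH (>= 50% id) but fails the 65% clustering identity
        hits = [
            SimilarityHit("A|g", "B|g", 60.0, 200, 1e-60, 350.0),
            SimilarityHit("B|g", "A|g", 60.0, 200, 1e-60, 350.0),
        ]
        pairs = best_bidirectional_hits(hits, PARAMS, strain_map(proteomes))
        assert pairs  # BBBH keeps the pair
        clusters = cluster_orthologs(pairs, hits, PARAMS, proteomes)
        assert len(clusters) == 2  # clustering stage rejects the edge

    def test_short_alignments_are_dropped(self):
        proteomes = {
            "A": [GeneRecord("g", "A", "p", "M" * 100)],
            "B": [GeneRecord("g", "B", "p", "M" * 100)],
        }
        hits = [
            SimilarityHit("A|g", "B|g", 90.0, 64, 1e-60, 350.0),
            SimilarityHit("B|g", "A|g", 90.0, 64, 1e-60, 350.0),
        ]
        pairs = best_bidirectional_hits(hits, PARAMS, strain_map(proteomes))
        clusters = cluster_orthologs(pairs, hits, PARAMS, proteomes)
        assert len(clusters) == 2

    def test_membership_is_a_partition_of_non_mge_genes(self, identical_proteomes):
        proteomes, _ = identical_proteomes
        hits = all_vs_all_hits(proteomes)
        pairs = best_bidirectional_hits(hits, PARAMS, strain_map(proteomes))
        clusters = cluster_orthologs(pairs, hits, PARAMS, proteomes)
        placed = [f"{s}|{g}" for c in clusters for s, g in c.members]
        everyone = [r.key for recs in proteomes.values() for r in recs]
        assert sorted(placed) == sorted(everyone)

    def test_zero_divergence_recovery_is_exact(self, identical_proteomes):
        proteomes, truth = identical_proteomes
        hits = all_vs_all_hits(proteomes)
        pairs = best_bidirectional_hits(hits, PARAMS, strain_map(proteomes))
        clusters = cluster_orthologs(pairs, hits, PARAMS, proteomes)
        recovered = {
            frozenset(f"{s}|{g}" for s, g in c.members) for c in clusters
        }
        true_clusters = {}
        for key, cid in truth.gene_to_cluster.items():
            true_clusters.setdefault(cid, set()).add(key)
        assert recovered == {frozenset(v) for v in true_clusters.values()}

    def test_imported_table_equals_built_in_engine(
        self, identical_proteomes, tmp_path
    ):
        """The BBBH set must not depend on the similarity engine."""
        proteomes, _ = identical_proteomes
        smap = strain_map(proteomes)
        builtin = all_vs_all_hits(proteomes)
        path = tmp_path / "hits.tsv"
        write_similarity_table(builtin, path)
        imported = validate_imported_hits(read_similarity_table(path), proteomes)
        assert best_bidirectional_hits(builtin, PARAMS, smap) == \
            best_bidirectional_hits(imported, PARAMS, smap)

    def test_imported_table_with_unknown_gene_errors(self, identical_proteomes):
        proteomes, _ = identical_proteomes
        rogue = [SimilarityHit("Z|nope", "S1|C00000_S1", 90.0, 100, 1e-40, 200.0)]
        with pytest.raises(ValueError, match="unknown gene"):
            validate_imported_hits(rogue, proteomes)

    def test_raising_identity_threshold_never_grows_clusters(
        self, identical_proteomes
    ):
        proteomes, _ = identical_proteomes
        hits = all_vs_all_hits(proteomes)
        sizes = []
        for ident in (65.0, 90.0, 100.0):
            params = ClusteringParams(cluster_min_identity=ident)
            pairs = best_bidirectional_hits(hits, params, strain_map(proteomes))
            clusters = cluster_orthologs(pairs, hits, params, proteomes)
            sizes.append(sorted((c.size for c in clusters), reverse=True))
        for looser, stricter in zip(sizes, sizes[1:]):
            assert len(stricter) >= len(looser)
            assert max(stricter) <= max(looser)


def oracle_partition_score(nodes, edges, strain_of):
    """Brute force: enumerate every one-per-strain partition, return the
    maximum total retained edge weight."""
    best = [0.0]
    ordered = sorted(nodes)

    def rec(i, groups, score):
        if i == len(ordered):
            best[0] = max(best[0], score)
            return
        node = ordered[i]
        strain = strain_of[node]
        rec(i + 1, groups + [({node}, {strain})], score)
        for members, strains in groups:
            if strain in strains:
                continue
            gain = sum(
                w for (u, v), w in edges.items()
                if (u == node and v in members) or (v == node and u in members)
            )
            members.add(node)
            strains.add(strain)
            rec(i + 1, groups, score + gain)
            members.remove(node)
            strains.remove(strain)

    rec(0, [], 0.0)
    return best[0]


def _random_bbbh_instance(seed):
    """<= 12 genes over 4 strains with random reciprocal hits."""
    rng = np.random.default_rng(seed)
    strains = ["A", "B", "C", "D"]
    proteomes = {
        s: [GeneRecord(f"g{i}", s, "p", "M" * 100)
            for i in range(rng.integers(1, 4))]
        for s in strains
    }
    genes = [(s, r) for s in strains for r in proteomes[s]]
    hits = []
    for (s1, r1), (s2, r2) in itertools.combinations(genes, 2):
        if s1 == s2 or rng.random() > 0.6:
            continue
        bit = float(rng.integers(100, 400))
        hits.append(SimilarityHit(r1.key, r2.key, 90.0, 100, 1e-40, bit))
        hits.append(SimilarityHit(r2.key, r1.key, 90.0, 100, 1e-40, bit))
    return proteomes, hits


def test_greedy_split_matches_brute_force_on_most_instances():
    """The greedy one-per-strain split should reach the optimal retained
    bit score on nearly all small random instances (mismatches allowed but
    rare, and logged)."""
    matches, mismatches = 0, []
    for seed in range(50):
        proteomes, hits = _random_bbbh_instance(seed)
        smap = strain_map(proteomes)
        pairs = best_bidirectional_hits(hits, PARAMS, smap)
        per = {(h.query_id, h.subject_id): h for h in hits}
        edges = {}
        for pair in pairs:
            a, b = sorted(pair)
            edges[(a, b)] = min(per[(a, b)].bit_score, per[(b, a)].bit_score)
        clusters = cluster_orthologs(pairs, hits, PARAMS, proteomes)
        greedy = sum(w for c in clusters for (_, _, w) in c.support)
        optimal = oracle_partition_score(set(smap), edges, smap)
        assert greedy <= optimal + 1e-9
        if abs(greedy - optimal) < 1e-9:
            matches += 1
        else:
            mismatches.append((seed, greedy, optimal))
    if mismatches:
        print(f"greedy/oracle mismatches: {mismatches}")
    assert matches >= 45


def test_divergent_clusters_still_recovered():
    """At ~90% within-cluster identity nearly all true clusters survive the
    65% identity threshold."""
    cfg = PanSimConfig(n_strains=5, n_core=50, n_dispensable=0,
                       n_unique_per_strain=0, within_cluster_divergence=0.1,
                       mean_protein_length=120, seed=7)
    proteomes, truth = simulate_proteomes(cfg)
    hits = all_vs_all_hits(proteomes)
    pairs = best_bidirectional_hits(hits, PARAMS, strain_map(proteomes))
    clusters = cluster_orthologs(pairs, hits, PARAMS, proteomes)
    recovered = Counter(frozenset(c.strains) for c in clusters)
    assert recovered[frozenset("S%d" % i for i in range(1, 6))] >= 48
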