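"""Ortholog clustering from all-vs-all protein similarity.

The pipeline follows the reciprocal-best-hit recipe: mobile genetic
elements are removed by annotation keyword, an all-vs-all local-alignment
search produces one best hit per ordered cross-strain gene pair, Best
Bidirectional Hits (BBBH; E <= 1e-5, identity >= 50%) define candidate
ortholog edges, and clusters are connected components of the edges that
additionally clear the PanOCT-style thresholds (identity >= 65%, alignment
length >= 65 columns).  Components that would place two genes of the same
strain in one cluster are split greedily by removing the weakest edge on a
path connecting the conflicting genes.

The alignment engine is pluggable: the built-in engine is Smith-Waterman
via Bio.Align.PairwiseAligner (BLOSUM62, affine gaps 11/1) with a
Karlin-Altschul E-value; precomputed tabular hits can be imported instead
and the downstream result must not depend on which engine produced them.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from math import log

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from ._types import GeneRecord, OrthologCluster, SimilarityHit

logger = logging.getLogger(__name__)

#: Karlin-Altschul parameters for gapped BLOSUM62 (open 11, extend 1)
KA_LAMBDA = 0.267
KA_K = 0.041
LN2 = log(2.0)

DEFAULT_MGE_KEYWORDS = (
    "transposase",
    "integrase",
    "insertion sequence",
    "phage",
    "recombinase",
    "resolvase",
)


@dataclass
class ClusteringParams:
    """Thresholds of the two-stage ortholog-detection protocol.

    BBBH stage: E-value <= ``bbbh_e_max`` and identity >= ``bbbh_min_identity``.
    Clustering stage: identity >= ``cluster_min_identity`` over at least
    ``cluster_min_match_length`` alignment columns.  All cutoffs inclusive.
    """

    bbbh_e_max: float = 1e-5
    bbbh_min_identity: float = 50.0
    cluster_min_identity: float = 65.0
    cluster_min_match_length: int = 65
    mge_keywords: tuple[str, ...] = DEFAULT_MGE_KEYWORDS

    def __post_init__(self) -> None:
        for v in (self.bbbh_min_identity, self.cluster_min_identity):
            if not 0 <= v <= 100:
                raise ValueError(f"identity threshold {v} outside [0, 100]")
        if self.cluster_min_match_length < 1:
            raise ValueError("cluster_min_match_length must be >= 1")
        self.mge_keywords = tuple(k.lower() for k in self.mge_keywords)


def exclude_mges(
    records: list[GeneRecord], params: ClusteringParams
) -> list[GeneRecord]:
    """Drop records annotated as mobile genetic elements.

    A record is removed when its lowercased product contains any keyword;
    removed records get ``is_mge = True`` and per-keyword counts are logged.
    """
    kept: list[GeneRecord] = []
    removed = Counter()
    for rec in records:
        product = rec.product.lower()
        hit = next((k for k in params.mge_keywords if k in product), None)
        if hit is None:
            kept.append(rec)
        else:
            rec.is_mge = True
            removed[hit] += 1
    for keyword, n in sorted(removed.items()):
        logger.info("MGE exclusion: %d record(s) matched %r", n, keyword)
    if records and not kept:
        logger.warning("MGE exclusion removed every record")
    return kept


class ProteinAligner:
    """Smith-Waterman protein alignment with a Karlin-Altschul E-value.

    Scores with BLOSUM62 and affine gaps (open 11, extend 1); the bit score
    and E-value use the standard gapped parameters (lambda = 0.267,
    K = 0.041) with search space m*n for one sequence pair.  A k-mer
    prescreen (default k = 5) skips pairs without any shared word, which
    cannot reach significance at the BBBH thresholds.
    """

    def __init__(self, prescreen_k: int = 5):
        self.prescreen_k = prescreen_k
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        self._aligner.open_gap_score = -11.0
        self._aligner.extend_gap_score = -1.0

    @staticmethod
    def _kmers(seq: str, k: int) -> set[str]:
        return {seq[i:i + k] for i in range(len(seq) - k + 1)}

    def align(self, query: GeneRecord, subject: GeneRecord) -> SimilarityHit | None:
        """Best local alignment as a SimilarityHit, or None if none scores > 0."""
        score = self._aligner.score(query.sequence, subject.sequence)
        if score <= 0:
            return None
        bit = (KA_LAMBDA * score - log(KA_K)) / LN2
        if bit <= 0:
            return None
        e_value = query.length * subject.length * 2.0 ** (-bit)
        aln = self._aligner.align(query.sequence, subject.sequence)[0]
        counts = aln.counts()
        columns = aln.length
        identity = 100.0 * counts.identities / columns if columns else 0.0
        return SimilarityHit(
            query_id=query.key,
            subject_id=subject.key,
            pct_identity=identity,
            align_length=columns,
            e_value=e_value,
            bit_score=bit,
        )

    def search(
        self, queries: list[GeneRecord], subjects: list[GeneRecord]
    ) -> list[SimilarityHit]:
        """One best hit per (query, subject) pair passing the prescreen."""
        k = self.prescreen_k
        index: dict[str, list[int]] = {}
        for j, rec in enumerate(subjects):
            for kmer in self._kmers(rec.sequence, k):
                index.setdefault(kmer, []).append(j)
        hits: list[SimilarityHit] = []
        for q in queries:
            candidates = sorted(
                {j for kmer in self._kmers(q.sequence, k) for j in index.get(kmer, ())}
            )
            for j in candidates:
                hit = self.align(q, subjects[j])
                if hit is not None:
                    hits.append(hit)
        return hits


def strain_map(proteomes: dict[str, list[GeneRecord]]) -> dict[str, str]:
    """Map globally unique gene key -> strain id."""
    return {rec.key: strain for strain, records in proteomes.items() for rec in records}


def all_vs_all_hits(
    proteomes: dict[str, list[GeneRecord]],
    aligner: ProteinAligner | None = None,
) -> list[SimilarityHit]:
    """All-vs-all cross-strain search with the built-in engine.

    Returns one best hit (highest bit score) per ordered cross-strain gene
    pair; within-strain pairs are never aligned because the BBBH criterion
    is defined across strains only.
    """
    if len(proteomes) < 2:
        raise ValueError("all-vs-all search needs at least 2 strains")
    aligner = aligner or ProteinAligner()
    hits: list[SimilarityHit] = []
    strains = sorted(proteomes)
    for a, b in combinations(strains, 2):
        hits.extend(aligner.search(proteomes[a], proteomes[b]))
        hits.extend(aligner.search(proteomes[b], proteomes[a]))
    return hits


def validate_imported_hits(
    hits: list[SimilarityHit], proteomes: dict[str, list[GeneRecord]]
) -> list[SimilarityHit]:
    """Check an imported similarity table against the loaded proteomes.

    Gene ids must use the ``strain|gene`` form; self-hits and within-strain
    hits are dropped (flagged in the log), unknown genes are an error.
    """
    known = strain_map(proteomes)
    kept = []
    n_self = 0
    for h in hits:
        for gid in (h.query_id, h.subject_id):
            if gid not in known:
                raise ValueError(
                    f"imported hit references unknown gene {gid!r} "
                    "(expected strain|gene ids present in the proteomes)"
                )
        if h.is_self_hit or known[h.query_id] == known[h.subject_id]:
            n_self += 1
            continue
        kept.append(h)
    if n_self:
        logger.info("imported table: dropped %d self/within-strain hit(s)", n_self)
    return kept


def _best_per_ordered_pair(hits: list[SimilarityHit]) -> dict[tuple[str, str], SimilarityHit]:
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        prev = best.get(key)
        if prev is None or (h.bit_score, h.pct_identity) > (prev.bit_score, prev.pct_identity):
            best[key] = h
    return best


def best_bidirectional_hits(
    hits: list[SimilarityHit],
    params: ClusteringParams,
    strain_of: dict[str, str],
) -> set[frozenset]:
    """Reciprocal-best cross-strain gene pairs.

    Pair (a, b) survives iff b is a's top-bit-score hit within b's strain
    and vice versa, and both directions pass the BBBH E-value and identity
    thresholds.  Bit-score ties break by higher identity, then by
    lexicographically smallest gene id, so the result is deterministic.
    """
    per_pair = _best_per_ordered_pair(hits)
    # best subject per (query, target strain)
    best_in_strain: dict[tuple[str, str], SimilarityHit] = {}
    for (q, s), h in sorted(per_pair.items()):
        target = strain_of[s]
        key = (q, target)
        prev = best_in_strain.get(key)
        if prev is None:
            best_in_strain[key] = h
            continue
        # maximise (bit, identity); among exact ties prefer the smaller id
        cand = (h.bit_score, h.pct_identity, [ord(c) for c in h.subject_id])
        incumbent = (prev.bit_score, prev.pct_identity, [ord(c) for c in prev.subject_id])
        if (cand[0], cand[1]) > (incumbent[0], incumbent[1]) or (
            (cand[0], cand[1]) == (incumbent[0], incumbent[1]) and cand[2] < incumbent[2]
        ):
            best_in_strain[key] = h

    def passes(h: SimilarityHit) -> bool:
        return h.e_value <= params.bbbh_e_max and h.pct_identity >= params.bbbh_min_identity

    pairs: set[frozenset] = set()
    for (q, target), h in best_in_strain.items():
        b = h.subject_id
        back = best_in_strain.get((b, strain_of[q]))
        if back is None or back.subject_id != q:
            continue
        if passes(h) and passes(back):
            pairs.add(frozenset((q, b)))
    return pairs


def _edge_weight(h1: SimilarityHit, h2: SimilarityHit) -> float:
    # conservative support: the weaker of the two directional bit scores
    return min(h1.bit_score, h2.bit_score)


def cluster_orthologs(
    bbbh_pairs: set[frozenset],
    hits: list[SimilarityHit],
    params: ClusteringParams,
    proteomes: dict[str, list[GeneRecord]],
) -> list[OrthologCluster]:
    """Connected-component clustering of the thresholded BBBH graph.

    Edges are kept only when both directional hits clear the clustering
    identity and match-length cutoffs.  Each connected component is then
    partitioned into one-member-per-strain groups by a greedy that
    maximises the retained edge bit score: best-gain pair agglomeration
    followed by single-gene relocation refinement.  A conflict-free
    component always collapses to a single cluster.  Every gene absent
    from the graph becomes a singleton cluster, so the result is a
    partition of the non-MGE genes.
    """
    strain_of = strain_map(proteomes)
    per_pair = _best_per_ordered_pair(hits)

    def clears(h: SimilarityHit | None) -> bool:
        return (
            h is not None
            and h.pct_identity >= params.cluster_min_identity
            and h.align_length >= params.cluster_min_match_length
        )

    graph = nx.Graph()
    for pair in sorted(bbbh_pairs, key=sorted):
        a, b = sorted(pair)
        fwd, rev = per_pair.get((a, b)), per_pair.get((b, a))
        if clears(fwd) and clears(rev):
            graph.add_edge(a, b, weight=_edge_weight(fwd, rev))

    placed: set[str] = set()
    clusters: list[OrthologCluster] = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    for comp_nodes in components:
        sub = graph.subgraph(comp_nodes)
        for nodes in _partition_component(sub, strain_of):
            members = {(strain_of[n], n.split("|", 1)[1]) for n in nodes}
            support = [
                (u, v, d["weight"])
                for u, v, d in graph.subgraph(nodes).edges(data=True)
            ]
            cl = OrthologCluster(cluster_id="", members=members, support=support)
            clusters.append(cl)
            placed.update(nodes)

    for strain in sorted(proteomes):
        for rec in proteomes[strain]:
            if rec.key not in placed:
                clusters.append(
                    OrthologCluster(cluster_id="", members={(strain, rec.gene_id)})
                )

    clusters.sort(key=lambda c: (-c.size, min(f"{s}|{g}" for s, g in c.members)))
    width = max(5, len(str(len(clusters))))
    for i, cl in enumerate(clusters):
        cl.cluster_id = f"CL{i:0{width}d}"
        cl.validate()
    return clusters


def _partition_component(sub: nx.Graph, strain_of: dict[str, str]) -> list[list[str]]:
    """Split one component into strain-disjoint groups, greedily maximising
    the total retained edge bit score.

    Starts from singletons, repeatedly merges the strain-disjoint group
    pair with the largest positive cross-edge weight, then refines by
    relocating single genes while any move increases the retained score.
    Ties break on sorted node order, so the result is deterministic.
    """
    nodes = sorted(sub.nodes)
    adj: dict[str, dict[str, float]] = {n: {} for n in nodes}
    for u, v, d in sub.edges(data=True):
        adj[u][v] = d["weight"]
        adj[v][u] = d["weight"]

    groups: dict[int, set[str]] = {i: {n} for i, n in enumerate(nodes)}
    strains: dict[int, set[str]] = {i: {strain_of[n]} for i, n in enumerate(nodes)}

    def cross_weight(ci: int, cj: int) -> float:
        return sum(
            adj[u].get(v, 0.0) for u in groups[ci] for v in groups[cj]
        )

    while True:
        best: tuple[float, int, int] | None = None
        keys = sorted(groups)
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                ci, cj = keys[a], keys[b]
                if strains[ci] & strains[cj]:
                    continue
                g = cross_weight(ci, cj)
                if g > 0 and (best is None or g > best[0]):
                    best = (g, ci, cj)
        if best is None:
            break
        _, ci, cj = best
        groups[ci] |= groups.pop(cj)
        strains[ci] |= strains.pop(cj)

    member_of = {n: ci for ci, mem in groups.items() for n in mem}
    improved = True
    while improved:
        improved = False
        for n in nodes:
            cur = member_of[n]
            stay = sum(adj[n].get(v, 0.0) for v in groups[cur] if v != n)
            move: tuple[float, int] | None = None
            for cj in sorted(groups):
                if cj == cur or strain_of[n] in strains[cj]:
                    continue
                g = sum(adj[n].get(v, 0.0) for v in groups[cj])
                if g > stay and (move is None or g > move[0]):
                    move = (g, cj)
            if move is not None:
                groups[cur].discard(n)
                strains[cur] = {strain_of[v] for v in groups[cur]}
                if not groups[cur]:
                    groups.pop(cur)
                    strains.pop(cur)
                groups[move[1]].add(n)
                strains[move[1]].add(strain_of[n])
                member_of[n] = move[1]
                improved = True
    return sorted((sorted(mem) for mem in groups.values()), key=lambda m: m[0])


def write_clusters_tsv(clusters: list[OrthologCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tstrain_id\tgene_id\n")
        for cl in clusters:
            for strain, gene in sorted(cl.members):
                fh.write(f"{cl.cluster_id}\t{strain}\t{gene}\n")


def read_clusters_tsv(path) -> list[OrthologCluster]:
    by_id: dict[str, OrthologCluster] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("cluster_id"):
            raise ValueError(f"{path}: missing cluster TSV header")
        for line in fh:
            cid, strain, gene = line.rstrip("\n").split("\t")
            by_id.setdefault(cid, OrthologCluster(cluster_id=cid)).members.add(
                (strain, gene)
            )
    return [by_id[k] for k in sorted(by_id)]
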