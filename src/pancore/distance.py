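"""Genome-to-genome distances from HSP statistics, plus TETRA correlation.

The distances follow the digital DDH formulation: with H_XY the total
length of all high-scoring segment pairs (HSPs) between genomes X and Y,
I_XY the number of identical base pairs over all HSPs, and
lambda(X, Y) = len(X) + len(Y),

    d1 = 1 - 2 * H_XY / lambda        (coverage-based)
    d2 = 1 - 2 * I_XY / lambda        (identity-based)

so identical genomes score 0 and unrelated genomes 1.  HSPs come either
from the built-in finder — exact k-mer seeds (default k = 15), ungapped
extension with an X-drop, minimum HSP length 100 bp — or from an imported
12-column tabular alignment file.  Overlapping HSPs are trimmed on the
query so each query position contributes at most once to H_XY and I_XY.

tetra_correlation computes the tetranucleotide-signature screen: Pearson
correlation of the 256 z-scores of observed vs Markov-expected 4-mer
counts, with conspecific genomes expected to correlate at >= 0.99.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import warnings

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from skbio import TreeNode

Genome = list[tuple[str, str]]  # ordered (contig_id, sequence)

_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_SEED_K = 15
DEFAULT_MIN_HSP = 100
DEFAULT_XDROP = 20
MATCH_SCORE = 1
MISMATCH_SCORE = -2


@dataclass
class HSPSet:
    """Aggregate HSP statistics between two genomes (one search direction)."""

    h_xy: int  # total HSP alignment length, bp
    i_xy: int  # identical base pairs over all HSPs
    len_x: int
    len_y: int

    def __post_init__(self) -> None:
        if not 0 <= self.i_xy <= self.h_xy:
            raise ValueError("need 0 <= I_XY <= H_XY")
        if self.h_xy > self.len_x + self.len_y:
            raise ValueError("H_XY exceeds the summed genome lengths")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    @property
    def lam(self) -> int:
        """lambda(X, Y): sum of both genome lengths."""
        return self.len_x + self.len_y


def _encode(seq: str) -> np.ndarray:
    return np.array([_NT_CODE[c] for c in seq], dtype=np.int8)


def _extend(
    q: np.ndarray, s: np.ndarray, q_pos: int, s_pos: int, k: int, xdrop: int
) -> tuple[int, int, int]:
    """Ungapped X-drop extension of a seed; returns (q_start, q_end, identities)."""
    # rightward from the seed end
    m = min(len(q) - (q_pos + k), len(s) - (s_pos + k))
    right = 0
    if m > 0:
        eq = (q[q_pos + k:q_pos + k + m] == s[s_pos + k:s_pos + k + m]) & (
            q[q_pos + k:q_pos + k + m] != _NT_CODE["N"]
        )
        steps = np.where(eq, MATCH_SCORE, MISMATCH_SCORE)
        cum = np.cumsum(steps)
        peak = np.maximum.accumulate(cum)
        dropped = np.nonzero(peak - cum > xdrop)[0]
        stop = dropped[0] if dropped.size else m
        right = int(np.argmax(cum[:stop]) + 1) if stop > 0 and cum[:stop].max() > 0 else 0
    # leftward from the seed start
    m = min(q_pos, s_pos)
    left = 0
    if m > 0:
        eq = (q[q_pos - m:q_pos][::-1] == s[s_pos - m:s_pos][::-1]) & (
            q[q_pos - m:q_pos][::-1] != _NT_CODE["N"]
        )
        steps = np.where(eq, MATCH_SCORE, MISMATCH_SCORE)
        cum = np.cumsum(steps)
        peak = np.maximum.accumulate(cum)
        dropped = np.nonzero(peak - cum > xdrop)[0]
        stop = dropped[0] if dropped.size else m
        left = int(np.argmax(cum[:stop]) + 1) if stop > 0 and cum[:stop].max() > 0 else 0
    return q_pos - left, q_pos + k + right, 0  # identities filled by caller


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit codes of all k-mers; -1 where the window contains N."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        window = arr[i:i + n].astype(np.int64)
        codes = codes * 4 + np.where(window == 4, 0, window)
        bad |= window == 4
    codes[bad] = -1
    return codes


def _find_hsps(
    query: np.ndarray, subject: np.ndarray, k: int, min_len: int, xdrop: int
) -> list[tuple[int, int, int]]:
    """Maximal ungapped HSPs as (q_start, q_end, s_start) triples."""
    subj_codes = _kmer_codes(subject, k)
    index: dict[int, list[int]] = {}
    for pos, code in enumerate(subj_codes):
        if code >= 0:
            index.setdefault(int(code), []).append(pos)
    query_codes = _kmer_codes(query, k)
    # per-diagonal end of the last extension, to skip seeds already covered
    diag_end: dict[int, int] = {}
    hsps: list[tuple[int, int, int]] = []
    for q_pos, code in enumerate(query_codes):
        if code < 0 or int(code) not in index:
            continue
        for s_pos in index[int(code)]:
            diag = q_pos - s_pos
            if diag_end.get(diag, -1) >= q_pos + k:
                continue
            q_start, q_end, _ = _extend(query, subject, q_pos, s_pos, k, xdrop)
            diag_end[diag] = q_end
            if q_end - q_start >= min_len:
                hsps.append((q_start, q_end, q_start - diag))
    return hsps


def compute_hsp_set(
    x: Genome,
    y: Genome,
    k: int = DEFAULT_SEED_K,
    min_hsp_length: int = DEFAULT_MIN_HSP,
    xdrop: int = DEFAULT_XDROP,
    imported_hsps: list[tuple[int, int, int, str, str]] | None = None,
) -> HSPSet:
    """Aggregate HSP statistics with X as subject and Y as query.

    Overlapping HSPs are resolved on the query: HSPs are visited longest
    first and positions already counted are excluded, so
    ``H_XY <= len(Y)`` and every query base contributes at most once.
    """
    len_x = sum(len(s) for _, s in x)
    len_y = sum(len(s) for _, s in y)
    if len_x == 0 or len_y == 0:
        raise ValueError("both genomes must be non-empty")
    shortest = min(len(s) for _, s in x + y)
    if k > shortest:
        raise ValueError(f"seed length k={k} exceeds shortest contig ({shortest} bp)")

    h_total = 0
    i_total = 0
    for q_id, q_seq in y:
        q_arr = _encode(q_seq)
        covered = np.zeros(q_arr.size, dtype=bool)
        for s_id, s_seq in x:
            s_arr = _encode(s_seq)
            hsps = _find_hsps(q_arr, s_arr, k, min_hsp_length, xdrop)
            hsps.sort(key=lambda t: (-(t[1] - t[0]), t[0]))
            for q_start, q_end, s_start in hsps:
                span = np.arange(q_start, q_end)
                fresh = ~covered[q_start:q_end]
                if not fresh.any():
                    continue
                covered[q_start:q_end] |= fresh
                qs = span[fresh]
                ss = qs - (q_start - s_start)
                eq = (q_arr[qs] == s_arr[ss]) & (q_arr[qs] != _NT_CODE["N"])
                h_total += int(fresh.sum())
                i_total += int(eq.sum())
    return HSPSet(h_xy=h_total, i_xy=i_total, len_x=len_x, len_y=len_y)


def distance_d1(hsp: HSPSet, doubled: bool = True) -> float:
    """Coverage-based distance 1 - 2*H_XY/lambda, clamped to [0, 1].

    ``doubled=False`` exposes the un-normalised variant 1 - H_XY/lambda,
    which cannot reach 0 even for identical genomes.
    """
    factor = 2.0 if doubled else 1.0
    return float(np.clip(1.0 - factor * hsp.h_xy / hsp.lam, 0.0, 1.0))


def distance_d2(hsp: HSPSet) -> float:
    """Identity-based distance 1 - 2*I_XY/lambda, clamped to [0, 1]."""
    return float(np.clip(1.0 - 2.0 * hsp.i_xy / hsp.lam, 0.0, 1.0))


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric S x S
    formula: str  # "d1" | "d2"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max() > 1e-12:
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).rename_axis(
            "strain"
        ).to_csv(path, sep="\t")

    def upgma_newick(self) -> str:
        """UPGMA dendrogram of the matrix in Newick format."""
        condensed = squareform(self.values, checks=False)
        Z = linkage(condensed, method="average")
        tree = TreeNode.from_linkage_matrix(Z, self.ids)
        return str(tree).strip()


def distance_matrix(
    genomes: dict[str, Genome], formula: str = "d2", **hsp_kwargs
) -> DistanceMatrix:
    """Pairwise distances, averaged over both search directions for symmetry."""
    ids = list(genomes)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate strain ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 genomes")
    if formula not in ("d1", "d2"):
        raise ValueError(f"unknown formula {formula!r}")
    dist = distance_d1 if formula == "d1" else distance_d2
    values = np.zeros((len(ids), len(ids)))
    for i, j in combinations(range(len(ids)), 2):
        fwd = dist(compute_hsp_set(genomes[ids[i]], genomes[ids[j]], **hsp_kwargs))
        rev = dist(compute_hsp_set(genomes[ids[j]], genomes[ids[i]], **hsp_kwargs))
        values[i, j] = values[j, i] = 0.5 * (fwd + rev)
    return DistanceMatrix(ids=ids, values=values, formula=formula)


def _tetra_zscores(genome: Genome) -> np.ndarray:
    """Z-scores of the 256 tetranucleotide counts vs a maximal-order Markov model.

    Counts are taken over both strands.  The expectation of each 4-mer
    w1w2w3w4 is n(w1w2w3) * n(w2w3w4) / n(w2w3), with the approximate
    variance of the corresponding maximal-order Markov null; zero-variance
    cells get a z-score of 0.
    """
    counts2 = np.zeros(4 ** 2)
    counts3 = np.zeros(4 ** 3)
    counts4 = np.zeros(4 ** 4)
    for _, seq in genome:
        for s in (seq, seq.translate(_COMPLEMENT)[::-1]):
            arr = _encode(s)
            for k, counts in ((2, counts2), (3, counts3), (4, counts4)):
                codes = _kmer_codes(arr, k)
                codes = codes[codes >= 0]
                counts += np.bincount(codes, minlength=4 ** k)
    z = np.zeros(256)
    for w in range(256):
        left3 = w >> 2
        right3 = w & 0x3F
        mid2 = (w >> 2) & 0xF
        n_mid = counts2[mid2]
        if n_mid == 0:
            continue
        exp = counts3[left3] * counts3[right3] / n_mid
        var = exp * (1 - counts3[left3] / n_mid) * (1 - counts3[right3] / n_mid)
        if var > 0:
            z[w] = (counts4[w] - exp) / np.sqrt(var)
    return z


def tetra_correlation(x: Genome, y: Genome) -> float:
    """Pearson correlation of the tetranucleotide z-score signatures."""
    for g in (x, y):
        total = sum(len(s) for _, s in g)
        if total < 4:
            raise ValueError("genome shorter than 4 bp")
        if total < 50_000:
            warnings.warn(
                "tetranucleotide signatures are unstable below ~50 kb",
                stacklevel=2,
            )
    zx, zy = _tetra_zscores(x), _tetra_zscores(y)
    if zx.std() == 0 or zy.std() == 0:
        raise ValueError("constant tetranucleotide signature; correlation undefined")
    r, _ = pearsonr(zx, zy)
    return float(r)
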