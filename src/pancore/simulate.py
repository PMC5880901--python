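"""Synthetic pan-genomes with known ground truth.

Three generators feed the downstream stages:

* :func:`simulate_profile` draws a presence/absence matrix directly —
  core rows are all-present, dispensable rows have i.i.d. Bernoulli(p)
  occupancy conditioned on being neither universal nor empty, and each
  strain contributes a block of strain-unique rows.
* :func:`simulate_proteomes` additionally emits protein sequences: each
  cluster descends from a random ancestral protein, and every member strain
  receives a copy mutated at per-site probability ``divergence``.
* :func:`simulate_genome_pair` builds two nucleotide genomes sharing a
  homologous block of known fraction and per-site divergence, with the
  analytic expectations the distance module should recover.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._types import GeneRecord
from .profile import PanProfile

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NT = np.array(list("ACGT"))

#: shortest protein emitted; keeps every full-length alignment above the
#: 65-column clustering cutoff
MIN_PROTEIN_LENGTH = 65

MGE_PRODUCTS = (
    "IS21 family transposase",
    "site-specific integrase",
    "phage major capsid protein",
    "tyrosine recombinase XerC",
)


@dataclass
class PanSimConfig:
    """Study conditions for the synthetic pan-genome.

    Defaults mirror a five-strain species with a 1,779-cluster core, 300
    dispensable clusters at 50% occupancy and ~60 strain-unique genes per
    strain; within-cluster divergence 0.1 gives ~90% within-cluster identity.
    """

    n_strains: int = 5
    n_core: int = 1779
    n_dispensable: int = 300
    dispensable_presence_prob: float = 0.5
    n_unique_per_strain: int = 60
    mean_protein_length: int = 300
    within_cluster_divergence: float = 0.1
    n_mge_per_strain: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        if not 0.0 < self.dispensable_presence_prob < 1.0:
            raise ValueError("dispensable_presence_prob must be in (0, 1)")
        if min(self.n_core, self.n_dispensable, self.n_unique_per_strain) < 0:
            raise ValueError("cluster counts must be >= 0")
        if not 0.0 <= self.within_cluster_divergence < 1.0:
            raise ValueError("within_cluster_divergence must be in [0, 1)")
        if self.mean_protein_length < MIN_PROTEIN_LENGTH:
            raise ValueError(
                f"mean_protein_length must be >= {MIN_PROTEIN_LENGTH} "
                "(shorter proteins cannot clear the 65-column match cutoff)"
            )

    @property
    def strain_ids(self) -> list[str]:
        return [f"S{i+1}" for i in range(self.n_strains)]


@dataclass
class SimTruth:
    """Ground-truth clustering of a simulated pan-genome."""

    gene_to_cluster: dict[str, str] = field(default_factory=dict)  # strain|gene -> cluster
    cluster_occupancy: dict[str, frozenset] = field(default_factory=dict)
    n_core: int = 0
    n_dispensable: int = 0  # includes unique clusters
    n_unique: int = 0

    @property
    def n_clusters(self) -> int:
        return self.n_core + self.n_dispensable

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tstrain_id\ttrue_cluster\n")
            for key in sorted(self.gene_to_cluster):
                strain, gene = key.split("|", 1)
                fh.write(f"{gene}\t{strain}\t{self.gene_to_cluster[key]}\n")


def _occupancy_rows(config: PanSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Occupancy matrix over truth clusters, in core/dispensable/unique order."""
    S = config.n_strains
    rows = [np.ones((config.n_core, S), dtype=bool)]
    p = config.dispensable_presence_prob
    disp = np.empty((config.n_dispensable, S), dtype=bool)
    for i in range(config.n_dispensable):
        while True:
            row = rng.random(S) < p
            if 0 < row.sum() < S:  # resample universal/empty draws
                disp[i] = row
                break
    rows.append(disp)
    uniq = np.zeros((S * config.n_unique_per_strain, S), dtype=bool)
    for j in range(S):
        uniq[j * config.n_unique_per_strain:(j + 1) * config.n_unique_per_strain, j] = True
    rows.append(uniq)
    return np.vstack(rows)


def _truth_from_occupancy(config: PanSimConfig, occ: np.ndarray) -> SimTruth:
    strains = config.strain_ids
    truth = SimTruth(n_core=config.n_core)
    cluster_ids = [f"C{i:05d}" for i in range(occ.shape[0])]
    for cid, row in zip(cluster_ids, occ):
        members = frozenset(s for s, pres in zip(strains, row) if pres)
        truth.cluster_occupancy[cid] = members
        for s in members:
            truth.gene_to_cluster[f"{s}|{cid}_{s}"] = cid
    occupancy = occ.sum(axis=1)
    truth.n_dispensable = int((occupancy < config.n_strains).sum())
    truth.n_unique = int((occupancy == 1).sum())
    return truth


def simulate_profile(config: PanSimConfig) -> tuple[PanProfile, SimTruth]:
    """Draw a presence/absence matrix with known partition counts."""
    rng = np.random.default_rng(config.seed)
    occ = _occupancy_rows(config, rng)
    if occ.shape[0] == 0:
        raise ValueError("config produces an empty profile")
    truth = _truth_from_occupancy(config, occ)
    profile = PanProfile(
        strains=config.strain_ids,
        matrix=occ,
        cluster_ids=list(truth.cluster_occupancy),
    )
    return profile, truth


def _random_protein(rng: np.random.Generator, mean_length: int) -> str:
    # geometric tail on top of the 65-residue floor; mean == mean_length
    extra = rng.geometric(1.0 / (mean_length - MIN_PROTEIN_LENGTH + 1)) - 1
    length = MIN_PROTEIN_LENGTH + int(extra)
    return "".join(rng.choice(AA, size=length))


def _substitute(
    arr: np.ndarray, alphabet: np.ndarray, divergence: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-site substitution, uniform over the other alphabet letters.

    Implemented as a cyclic offset draw so a substituted site never keeps
    its original letter.
    """
    if divergence == 0.0 or arr.size == 0:
        return arr
    out = arr.copy()
    lookup = {c: i for i, c in enumerate(alphabet)}
    codes = np.array([lookup[c] for c in arr])
    hit = np.where(rng.random(arr.size) < divergence)[0]
    offsets = rng.integers(1, len(alphabet), size=hit.size)
    out[hit] = alphabet[(codes[hit] + offsets) % len(alphabet)]
    return out


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    return "".join(_substitute(arr, AA, divergence, rng))


def simulate_proteomes(
    config: PanSimConfig,
) -> tuple[dict[str, list[GeneRecord]], SimTruth]:
    """Emit per-strain proteomes whose true clustering is known.

    Cluster members are diverged copies of a common ancestral protein;
    unique genes are fresh random sequences.  ``n_mge_per_strain`` extra
    decoy genes per strain carry mobile-element product annotations and are
    *not* part of the truth clustering (the pipeline is expected to drop
    them before clustering).
    """
    rng = np.random.default_rng(config.seed)
    occ = _occupancy_rows(config, rng)
    truth = _truth_from_occupancy(config, occ)
    strains = config.strain_ids
    proteomes: dict[str, list[GeneRecord]] = {s: [] for s in strains}

    for cid, row in zip(truth.cluster_occupancy, occ):
        ancestor = _random_protein(rng, config.mean_protein_length)
        for s, present in zip(strains, row):
            if not present:
                continue
            seq = _mutate(ancestor, config.within_cluster_divergence, rng)
            proteomes[s].append(
                GeneRecord(
                    gene_id=f"{cid}_{s}",
                    strain_id=s,
                    product="hypothetical protein",
                    sequence=seq,
                )
            )
    for s in strains:
        for m in range(config.n_mge_per_strain):
            proteomes[s].append(
                GeneRecord(
                    gene_id=f"MGE{m:03d}_{s}",
                    strain_id=s,
                    product=MGE_PRODUCTS[m % len(MGE_PRODUCTS)],
                    sequence=_random_protein(rng, config.mean_protein_length),
                )
            )
    return proteomes, truth


def simulate_markov_genome(
    length: int,
    seed: int = 0,
    order: int = 3,
    concentration: float = 1.0,
) -> str:
    """A genome with genuine compositional signature: an order-``order``
    Markov chain with Dirichlet-drawn transition probabilities.

    Uniform-random sequence has no tetranucleotide structure beyond its
    dimer/trimer content, so its TETRA z-scores are pure sampling noise;
    a higher-order Markov chain produces the kind of oligonucleotide
    signature that makes conspecific genomes correlate near 1.  Lower
    ``concentration`` gives a stronger signature.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    rng = np.random.default_rng(seed)
    n_states = 4 ** order
    probs = rng.dirichlet(np.full(4, concentration), size=n_states)
    cum = np.cumsum(probs, axis=1)
    out = np.empty(length, dtype=np.int64)
    out[:order] = rng.integers(0, 4, size=order)
    state = 0
    for i in range(order):
        state = state * 4 + out[i]
    mask = n_states - 1
    draws = rng.random(length)
    for i in range(order, length):
        out[i] = np.searchsorted(cum[state], draws[i], side="right")
        state = ((state * 4) & mask) + out[i]
    return "".join(NT[out])


def mutate_genome(seq: str, divergence: float, seed: int = 0) -> str:
    """Per-site substituted copy of a nucleotide sequence."""
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    return "".join(_substitute(np.array(list(seq)), NT, divergence, rng))


def simulate_genome_pair(
    length: int,
    shared_fraction: float,
    divergence: float,
    seed: int = 0,
) -> tuple[str, str, dict[str, float]]:
    """Two genomes sharing a homologous block of known size and divergence.

    X is random; Y is a mutated copy of the first ``shared_fraction * length``
    bases of X followed by unrelated random sequence.  The returned
    expectations are ``E[I_XY] = f*L*(1-d)``, ``lambda = 2L`` and hence
    ``E[d2] = 1 - f*(1-d)``.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    x = rng.choice(NT, size=length)
    n_shared = int(round(shared_fraction * length))
    block = _substitute(x[:n_shared], NT, divergence, rng)
    tail = rng.choice(NT, size=length - n_shared)
    y = np.concatenate([block, tail])
    expected = {
        "e_i_xy": n_shared * (1.0 - divergence),
        "lambda": 2.0 * length,
        "e_d2": 1.0 - shared_fraction * (1.0 - divergence),
    }
    return "".join(x), "".join(y), expected
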