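"""Presence/absence matrix and the core/dispensable/unique partition.

The PanProfile is the pivot of the analysis: a boolean clusters x strains
matrix.  A cluster present in every strain is *core*; present in exactly one
strain, *unique* (strain-specific); anything absent from at least one strain
is *dispensable* — a superset that includes the unique clusters, so that
core + dispensable equals the pan-genome size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
import os

import numpy as np
import pandas as pd

from ._types import OrthologCluster

#: exhaustive-enumeration guard for subset-resolved operations
MAX_STRAINS = 12


@dataclass
class PanProfile:
    """Boolean presence/absence matrix, clusters x strains."""

    strains: list[str]
    matrix: np.ndarray  # bool, shape (n_clusters, S)
    cluster_ids: list[str]
    proteome_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.strains):
            raise ValueError("matrix shape does not match strain list")
        if self.matrix.shape[0] == 0:
            raise ValueError("empty profile")
        if len(self.strains) < 2:
            raise ValueError("a pan-genome profile needs at least 2 strains")
        if not self.matrix.any(axis=1).all():
            raise ValueError("profile has an all-absent cluster row")
        if len(self.cluster_ids) != self.matrix.shape[0]:
            raise ValueError("cluster_ids length does not match matrix")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def pan_size(self) -> int:
        """Pan-genome size = number of clusters (rows)."""
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.astype(int), index=self.cluster_ids, columns=self.strains
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().rename_axis("cluster_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "PanProfile":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            strains=list(df.columns),
            matrix=df.values.astype(bool),
            cluster_ids=[str(i) for i in df.index],
        )


@dataclass
class PartitionCounts:
    core: int
    dispensable: int
    unique: int
    per_strain_unique: dict[str, int]

    @property
    def pan(self) -> int:
        return self.core + self.dispensable


def build_profile(
    clusters: list[OrthologCluster],
    strains: list[str],
    proteome_sizes: dict[str, int] | None = None,
) -> PanProfile:
    """Assemble the presence/absence matrix from ortholog clusters.

    Rows are ordered by descending occupancy then cluster id, so the layout
    is deterministic regardless of clustering traversal order.
    """
    if not clusters:
        raise ValueError("empty profile: no clusters supplied")
    index = {s: j for j, s in enumerate(strains)}
    rows = []
    for cl in clusters:
        cl.validate()
        row = np.zeros(len(strains), dtype=bool)
        for strain_id, _ in cl.members:
            if strain_id not in index:
                raise ValueError(
                    f"cluster {cl.cluster_id}: strain {strain_id!r} not in strain list"
                )
            row[index[strain_id]] = True
        rows.append((row, cl.cluster_id))
    rows.sort(key=lambda t: (-int(t[0].sum()), t[1]))
    matrix = np.array([r for r, _ in rows], dtype=bool)
    ids = [cid for _, cid in rows]
    return PanProfile(
        strains=list(strains),
        matrix=matrix,
        cluster_ids=ids,
        proteome_sizes=dict(proteome_sizes or {}),
    )


def partition_profile(profile: PanProfile) -> PartitionCounts:
    """Partition the profile into core / dispensable / unique counts.

    Unique clusters are counted inside the dispensable genome, so
    ``core + dispensable == pan_size`` always holds.
    """
    occupancy = profile.matrix.sum(axis=1)
    core = int((occupancy == profile.n_strains).sum())
    unique_mask = occupancy == 1
    unique = int(unique_mask.sum())
    dispensable = profile.pan_size - core
    per_strain_unique = {
        s: int(profile.matrix[unique_mask, j].sum())
        for j, s in enumerate(profile.strains)
    }
    return PartitionCounts(core, dispensable, unique, per_strain_unique)


def core_fraction_per_strain(
    core_count: int, proteome_sizes: dict[str, int]
) -> tuple[dict[str, int], int, int]:
    """Percent of each strain's proteome that is core, half-up to integers.

    Returns the per-strain mapping plus the (min, max) bracket.
    """
    import warnings

    fractions: dict[str, int] = {}
    for strain, size in proteome_sizes.items():
        if size <= 0:
            raise ValueError(f"strain {strain!r}: proteome size must be > 0")
        if core_count > size:
            warnings.warn(
                f"core count {core_count} exceeds proteome size {size} of "
                f"{strain!r}: inconsistent inputs?",
                stacklevel=2,
            )
        pct = Decimal(100 * core_count) / Decimal(size)
        fractions[strain] = int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    values = list(fractions.values())
    return fractions, min(values), max(values)


def subset_counts(profile: PanProfile) -> dict[frozenset, int]:
    """Number of clusters whose occupancy is exactly each non-empty strain subset.

    This is the Venn-diagram decomposition: counts sum to the pan-genome size
    and the all-strains cell is the core count.
    """
    if profile.n_strains > MAX_STRAINS:
        raise ValueError(
            f"subset_counts enumerates 2^S - 1 cells; S={profile.n_strains} > "
            f"{MAX_STRAINS}. Aggregate strains first."
        )
    counts = {
        frozenset(sub): 0
        for n in range(1, profile.n_strains + 1)
        for sub in combinations(profile.strains, n)
    }
    for row in profile.matrix:
        key = frozenset(s for s, present in zip(profile.strains, row) if present)
        counts[key] += 1
    return counts
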