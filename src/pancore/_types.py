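"""Shared domain types for the pan-genome pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field


AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NT_ALPHABET = set("ACGTN")


@dataclass
class GeneRecord:
    """One annotated protein of one strain.

    ``gene_id`` is unique within a strain; the globally unique form is
    ``strain_id|gene_id``.  ``is_mge`` is set by the MGE-exclusion step,
    never by the parser.
    """

    gene_id: str
    strain_id: str
    product: str
    sequence: str
    is_mge: bool = False

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.gene_id!r}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.gene_id!r}: non-amino-acid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def key(self) -> str:
        """Globally unique identifier, ``strain_id|gene_id``."""
        return f"{self.strain_id}|{self.gene_id}"


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise local-alignment result (BLAST tabular semantics)."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.align_length < 1:
            raise ValueError(f"align_length {self.align_length} < 1")
        if self.e_value < 0:
            raise ValueError(f"e_value {self.e_value} < 0")
        if self.bit_score <= 0:
            raise ValueError(f"bit_score {self.bit_score} <= 0")

    @property
    def is_self_hit(self) -> bool:
        return self.query_id == self.subject_id


@dataclass
class OrthologCluster:
    """A set of putatively orthologous genes, at most one per strain."""

    cluster_id: str
    members: set[tuple[str, str]] = field(default_factory=set)  # (strain_id, gene_id)
    support: list[tuple[str, str, float]] = field(default_factory=list)  # retained edges

    @property
    def strains(self) -> set[str]:
        return {s for s, _ in self.members}

    @property
    def size(self) -> int:
        return len(self.members)

    def validate(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id}: empty")
        if len(self.strains) != len(self.members):
            raise ValueError(f"cluster {self.cluster_id}: two members share a strain")
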