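"""Core record types for gene-disease association (GDA) datasets.

A dataset couples a set of protein-bearing genes, a set of described
diseases, and a list of labeled (gene, disease) pairs. Pairs are keyed by
string identifiers, never by row order; duplicate pairs are hard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Closed protein alphabet: the 20 standard residues plus X for unknown.
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class GeneRecord:
    """A gene identified by an opaque key, carrying its protein sequence."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"gene {self.gene_id!r}: sequence must be non-empty")
        seq = self.sequence.upper()
        for pos, ch in enumerate(seq):
            if ch not in PROTEIN_ALPHABET:
                raise ValueError(
                    f"gene {self.gene_id!r}: invalid residue {ch!r} at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class DiseaseRecord:
    """A disease identified by an opaque key, with free-text name/description."""

    disease_id: str
    name: str
    description: str

    def __post_init__(self) -> None:
        if not self.disease_id:
            raise ValueError("disease_id must be non-empty")
        if not self.description.split():
            raise ValueError(
                f"disease {self.disease_id!r}: description must have >= 1 token"
            )


@dataclass(frozen=True)
class AssociationPair:
    """A labeled (gene, disease) pair, optionally carrying a predicted score."""

    gene_id: str
    disease_id: str
    label: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(
                f"pair ({self.gene_id}, {self.disease_id}): label must be 0 or 1, "
                f"got {self.label!r}"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(
                f"pair ({self.gene_id}, {self.disease_id}): score {self.score} "
                "outside [0, 1]"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_id, self.disease_id)


@dataclass
class AssociationDataset:
    """Genes, diseases and their labeled pairs, with optional CV fold labels.

    Invariants enforced on construction: every pair's identifiers resolve
    against the record maps, no (gene_id, disease_id) pair occurs twice, and
    fold indices (when present) cover one integer per pair.
    """

    genes: dict[str, GeneRecord]
    diseases: dict[str, DiseaseRecord]
    pairs: list[AssociationPair] = field(default_factory=list)
    fold_of_pair: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for p in self.pairs:
            if p.gene_id not in self.genes:
                raise KeyError(f"pair references unknown gene_id {p.gene_id!r}")
            if p.disease_id not in self.diseases:
                raise KeyError(f"pair references unknown disease_id {p.disease_id!r}")
            if p.key in seen:
                raise ValueError(f"duplicate pair ({p.gene_id}, {p.disease_id})")
            seen.add(p.key)
        if self.fold_of_pair is not None and len(self.fold_of_pair) != len(self.pairs):
            raise ValueError("fold_of_pair length must match number of pairs")

    @property
    def positive_pairs(self) -> list[AssociationPair]:
        return [p for p in self.pairs if p.label == 1]

    @property
    def pair_keys(self) -> set[tuple[str, str]]:
        return {p.key for p in self.pairs}

    def with_pairs(
        self,
        pairs: Iterable[AssociationPair],
        fold_of_pair: Optional[list[int]] = None,
    ) -> "AssociationDataset":
        """Return a copy of this dataset with a different pair list."""
        return AssociationDataset(
            genes=dict(self.genes),
            diseases=dict(self.diseases),
            pairs=list(pairs),
            fold_of_pair=fold_of_pair,
        )

    def subset(self, indices: Iterable[int]) -> "AssociationDataset":
        idx = list(indices)
        folds = None
        if self.fold_of_pair is not None:
            folds = [self.fold_of_pair[i] for i in idx]
        return self.with_pairs([self.pairs[i] for i in idx], folds)


def genes_from_records(records: Iterable[GeneRecord]) -> dict[str, GeneRecord]:
    out: dict[str, GeneRecord] = {}
    for r in records:
        if r.gene_id in out:
            raise ValueError(f"duplicate gene_id {r.gene_id!r}")
        out[r.gene_id] = r
    return out


def diseases_from_records(
    records: Iterable[DiseaseRecord],
) -> dict[str, DiseaseRecord]:
    out: dict[str, DiseaseRecord] = {}
    for r in records:
        if r.disease_id in out:
            raise ValueError(f"duplicate disease_id {r.disease_id!r}")
        out[r.disease_id] = r
    return out


__all__ = [
    "AMINO_ACIDS",
    "PROTEIN_ALPHABET",
    "GeneRecord",
    "DiseaseRecord",
    "AssociationPair",
    "AssociationDataset",
    "genes_from_records",
    "diseases_from_records",
]
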