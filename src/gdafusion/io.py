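"""Readers/writers for the package's file formats, negative sampling and folds.

Formats
-------
* protein sequences: FASTA (header token up to first whitespace = gene_id)
* associations: TSV ``gene_id <tab> disease_id <tab> label[ <tab> score]``,
  header optional (auto-detected by a non-numeric third field)
* disease text: TSV ``disease_id <tab> name <tab> description`` or JSON
* predictions: TSV with header ``gene_id <tab> disease_id <tab> score``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
from Bio import SeqIO
from sklearn.model_selection import StratifiedKFold

from .records import (
    AssociationDataset,
    AssociationPair,
    DiseaseRecord,
    GeneRecord,
    diseases_from_records,
    genes_from_records,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, GeneRecord]:
    """Read protein sequences from FASTA into GeneRecords keyed by gene_id.

    The FASTA id (header token up to the first whitespace) is the gene_id;
    sequences are uppercased. Duplicate ids and residues outside the
    20-letter alphabet (plus X) are hard errors.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA entries found")
    return genes_from_records(
        GeneRecord(gene_id=r.id, sequence=str(r.seq)) for r in records
    )


def write_fasta(path: PathLike, genes: dict[str, GeneRecord]) -> None:
    with open(path, "w") as fh:
        for g in genes.values():
            fh.write(f">{g.gene_id}\n{g.sequence}\n")


def read_diseases(path: PathLike) -> dict[str, DiseaseRecord]:
    """Read disease descriptions from TSV (id, name, description) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            entries = json.load(fh)
        if isinstance(entries, dict):
            entries = [
                {"disease_id": k, **v} if isinstance(v, dict) else
                {"disease_id": k, "name": k, "description": v}
                for k, v in entries.items()
            ]
        return diseases_from_records(
            DiseaseRecord(
                disease_id=e["disease_id"],
                name=e.get("name", e["disease_id"]),
                description=e["description"],
            )
            for e in entries
        )
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("disease_id", "id"):
                continue
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            records.append(
                DiseaseRecord(disease_id=parts[0], name=parts[1], description=parts[2])
            )
    if not records:
        raise ValueError(f"{path}: no disease records found")
    return diseases_from_records(records)


def write_diseases(path: PathLike, diseases: dict[str, DiseaseRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("disease_id\tname\tdescription\n")
        for d in diseases.values():
            fh.write(f"{d.disease_id}\t{d.name}\t{d.description}\n")


def _looks_like_header(fields: list[str]) -> bool:
    try:
        float(fields[2])
    except ValueError:
        return True
    return False


def read_associations(
    path: PathLike,
    genes: dict[str, GeneRecord],
    diseases: dict[str, DiseaseRecord],
) -> AssociationDataset:
    """Read a labeled association table against known gene/disease records.

    Unresolvable identifiers, labels outside {0, 1} and duplicated pairs are
    errors naming the offending row content.
    """
    path = Path(path)
    pairs: list[AssociationPair] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            if lineno == 1 and _looks_like_header(parts):
                continue
            gid, did, raw_label = parts[0], parts[1], parts[2]
            if raw_label not in ("0", "1"):
                raise ValueError(
                    f"{path}:{lineno}: label must be 0 or 1, got {raw_label!r}"
                )
            if gid not in genes:
                raise KeyError(f"{path}:{lineno}: unknown gene_id {gid!r}")
            if did not in diseases:
                raise KeyError(f"{path}:{lineno}: unknown disease_id {did!r}")
            if (gid, did) in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pair ({gid}, {did})")
            seen.add((gid, did))
            score = float(parts[3]) if len(parts) > 3 and parts[3] != "" else None
            pairs.append(
                AssociationPair(gene_id=gid, disease_id=did, label=int(raw_label),
                                score=score)
            )
    if not pairs:
        raise ValueError(f"{path}: no association rows found")
    return AssociationDataset(genes=dict(genes), diseases=dict(diseases), pairs=pairs)


def write_associations(path: PathLike, dataset: AssociationDataset) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdisease_id\tlabel\n")
        for p in dataset.pairs:
            fh.write(f"{p.gene_id}\t{p.disease_id}\t{p.label}\n")


def write_predictions(
    path: PathLike, pairs: Iterable[AssociationPair]
) -> None:
    """Write scored pairs as a prediction TSV (gene_id, disease_id, score)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tdisease_id\tscore\n")
        for p in pairs:
            if p.score is None:
                raise ValueError(f"pair ({p.gene_id}, {p.disease_id}) has no score")
            fh.write(f"{p.gene_id}\t{p.disease_id}\t{p.score:.10f}\n")


# ---------------------------------------------------------------------------
# negative sampling and cross-validation folds
# ---------------------------------------------------------------------------

def sample_negatives(
    dataset: AssociationDataset, ratio: float, seed: int
) -> AssociationDataset:
    """Augment a dataset with label-0 pairs sampled from the free complement.

    ``round(ratio * n_positives)`` pairs are drawn uniformly without
    replacement from the set of (gene, disease) combinations that do not
    already occur in the dataset, matching the evaluation protocol of
    drawing an equal number of non-overlapping negatives at ratio 1.
    """
    positives = dataset.positive_pairs
    if not positives:
        raise ValueError("dataset has no positive pairs to sample negatives for")
    n_needed = int(round(ratio * len(positives)))
    if n_needed == 0:
        return dataset
    gene_ids = sorted(dataset.genes)
    disease_ids = sorted(dataset.diseases)
    n_g, n_d = len(gene_ids), len(disease_ids)
    existing = dataset.pair_keys
    g_index = {g: i for i, g in enumerate(gene_ids)}
    d_index = {d: i for i, d in enumerate(disease_ids)}
    taken = np.zeros(n_g * n_d, dtype=bool)
    for (g, d) in existing:
        taken[g_index[g] * n_d + d_index[d]] = True
    free = np.flatnonzero(~taken)
    if len(free) < n_needed:
        raise ValueError(
            f"complement too small: requested {n_needed} negatives but only "
            f"{len(free)} free (gene, disease) combinations exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(free, size=n_needed, replace=False)
    new_pairs = list(dataset.pairs)
    for flat in sorted(int(c) for c in chosen):
        g = gene_ids[flat // n_d]
        d = disease_ids[flat % n_d]
        new_pairs.append(AssociationPair(gene_id=g, disease_id=d, label=0))
    return dataset.with_pairs(new_pairs)


def make_folds(
    dataset: AssociationDataset, k: int = 5, seed: int = 0
) -> AssociationDataset:
    """Assign each pair a fold index in 0..k-1, stratified by label.

    Fold sizes differ by at most one and each fold's positive count is within
    one pair of a proportional share, so small-sample metric estimates stay
    stable across folds.
    """
    n = len(dataset.pairs)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of pairs ({n})")
    labels = np.array([p.label for p in dataset.pairs])
    folds = np.empty(n, dtype=int)
    if len(np.unique(labels)) == 1:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        for f, test_idx in enumerate(np.array_split(perm, k)):
            folds[test_idx] = f
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
            folds[test_idx] = f
    return dataset.with_pairs(dataset.pairs, fold_of_pair=[int(f) for f in folds])


__all__ = [
    "read_fasta",
    "write_fasta",
    "read_diseases",
    "write_diseases",
    "read_associations",
    "write_associations",
    "write_predictions",
    "sample_negatives",
    "make_folds",
]
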