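"""Domain types, file readers/writers and id registries shared by all stages.

All indices are 0-based internally; on-disk artifacts are keyed by id so the
index convention never leaks into files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nnan")

SimilarityKind = Literal["drug_weighted", "drug_plain", "microbe"]

VALID_BASES = frozenset("ACGTN")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass(frozen=True)
class DrugRecord:
    """A drug identified by an opaque string id with a SMILES structure."""

    id: str
    smiles: str


@dataclass(frozen=True)
class MicrobeRecord:
    """A microbe identified by an opaque string id with a nucleotide sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"microbe {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - VALID_BASES
        if bad:
            raise DataError(
                f"microbe {self.id!r}: invalid characters {sorted(bad)} "
                "(alphabet is A/C/G/T/N)"
            )


@dataclass(frozen=True)
class RejectedRecord:
    """A record that failed validation at load time, with the reason."""

    id: str
    payload: str
    reason: str


@dataclass
class BipartiteAssociations:
    """The drug-microbe association graph G = (D, B, E).

    ``edges`` holds 0-based (drug index, microbe index) pairs into the two id
    registries.  ``fold_assignment`` optionally maps evaluated pairs (both
    positive and sampled negative) to a fold label.
    """

    drug_ids: list[str]
    microbe_ids: list[str]
    edges: set[tuple[int, int]]
    fold_assignment: dict[tuple[int, int], int] | None = None

    def __post_init__(self) -> None:
        m, n = len(self.drug_ids), len(self.microbe_ids)
        for di, mi in self.edges:
            if not (0 <= di < m and 0 <= mi < n):
                raise DataError(f"edge ({di}, {mi}) out of range for {m}x{n} graph")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_ids)

    @property
    def pair_universe_size(self) -> int:
        return self.n_drugs * self.n_microbes

    def drugs_of_microbe(self, microbe_index: int) -> set[int]:
        return {d for d, b in self.edges if b == microbe_index}

    def microbes_of_drug(self, drug_index: int) -> set[int]:
        return {b for d, b in self.edges if d == drug_index}

    def negatives(self) -> list[tuple[int, int]]:
        """All unlabeled pairs of the m*n universe, in row-major order."""
        return [
            (d, b)
            for d in range(self.n_drugs)
            for b in range(self.n_microbes)
            if (d, b) not in self.edges
        ]


@dataclass
class SimilarityMatrix:
    """Dense similarity matrix with an ordered id registry.

    ``drug_weighted`` matrices are directed (entry [i, j] uses drug i as the
    reference); ``drug_plain`` and ``microbe`` matrices are symmetric with a
    unit diagonal.
    """

    ids: list[str]
    values: np.ndarray
    kind: SimilarityKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.ids)
        if self.values.shape != (k, k):
            raise DataError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{k} ids"
            )
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise DataError("similarity entries must lie in [0, 1]")
        if self.kind in ("drug_plain", "microbe") and k:
            if not np.allclose(np.diag(self.values), 1.0):
                raise DataError(f"{self.kind} similarity must have unit diagonal")
            if self.kind == "microbe" and not np.allclose(self.values, self.values.T):
                raise DataError("microbe similarity must be symmetric")

    def index_of(self, node_id: str) -> int:
        try:
            return self.ids.index(node_id)
        except ValueError:
            raise KeyError(f"unknown id {node_id!r}") from None

    def symmetrized(self) -> "SimilarityMatrix":
        """Mean of the two directions; identity for already-symmetric kinds."""
        if self.kind != "drug_weighted":
            return self
        vals = (self.values + self.values.T) / 2.0
        return SimilarityMatrix(ids=list(self.ids), values=vals, kind="drug_weighted")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _check_unique_ids(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {what} id {i!r}")
        seen.add(i)


def load_drug_table(
    path: str | Path, format: str = "tsv_smiles"
) -> tuple[list[DrugRecord], list[RejectedRecord]]:
    """Load drugs from a TSV (``id<TAB>smiles``) or an SDF file.

    Molecules that fail to parse are collected into the returned rejection
    report rather than silently dropped.  Duplicate ids are a hard error.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    raw: list[tuple[str, str]] = []
    if format == "tsv_smiles":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise DataError(f"{path}:{lineno}: expected id<TAB>smiles")
                raw.append((parts[0], parts[1]))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False)
        for idx, mol in enumerate(supplier):
            if mol is None:
                raw.append((f"<record {idx}>", ""))
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"<record {idx}>"
            raw.append((name, Chem.MolToSmiles(mol)))
    else:
        raise ValueError(f"unknown drug table format {format!r}")

    _check_unique_ids([r[0] for r in raw], "drug")

    records: list[DrugRecord] = []
    rejected: list[RejectedRecord] = []
    for drug_id, smiles in raw:
        mol = Chem.MolFromSmiles(smiles) if smiles else None
        if mol is None:
            rejected.append(RejectedRecord(drug_id, smiles, "unparseable SMILES"))
        else:
            records.append(DrugRecord(id=drug_id, smiles=smiles))
    if not raw:
        logger.warning("drug table %s is empty", path)
    if rejected:
        logger.warning(
            "rejected %d of %d drug records: %s",
            len(rejected), len(raw), [r.id for r in rejected],
        )
    return records, rejected


def load_microbe_fasta(path: str | Path) -> list[MicrobeRecord]:
    """Load microbes from FASTA; the id is the header up to first whitespace."""
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [
        MicrobeRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    _check_unique_ids([r.id for r in records], "microbe")
    return records


def load_associations(
    path: str | Path,
    drug_registry: Sequence[str],
    microbe_registry: Sequence[str],
    unknown_id_policy: str = "skip",
) -> BipartiteAssociations:
    """Load a two-column TSV of (drug id, microbe id) association edges.

    Edges are deduplicated.  Rows naming unknown ids are skipped with a
    warning by default; ``unknown_id_policy='error'`` makes them fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if unknown_id_policy not in ("skip", "error"):
        raise ValueError(f"unknown_id_policy must be 'skip' or 'error'")

    d_index = {d: i for i, d in enumerate(drug_registry)}
    b_index = {b: i for i, b in enumerate(microbe_registry)}
    edges: set[tuple[int, int]] = set()
    n_rows = n_unknown = n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}:{lineno}: expected drug_id<TAB>microbe_id")
            n_rows += 1
            did, bid = parts[0], parts[1]
            if did not in d_index or bid not in b_index:
                n_unknown += 1
                msg = f"{path}:{lineno}: unknown id in row ({did!r}, {bid!r})"
                if unknown_id_policy == "error":
                    raise DataError(msg)
                logger.warning("%s; skipped", msg)
                continue
            edge = (d_index[did], b_index[bid])
            if edge in edges:
                n_dup += 1
            edges.add(edge)
    assoc = BipartiteAssociations(
        drug_ids=list(drug_registry), microbe_ids=list(microbe_registry), edges=edges
    )
    logger.info(
        "loaded associations: m=%d drugs, n=%d microbes, |E|=%d "
        "(%d rows, %d duplicates, %d unknown-id rows)",
        assoc.n_drugs, assoc.n_microbes, len(edges), n_rows, n_dup, n_unknown,
    )
    return assoc


def write_associations(assoc: BipartiteAssociations, path: str | Path) -> None:
    with open(path, "w") as fh:
        for d, b in sorted(assoc.edges):
            fh.write(f"{assoc.drug_ids[d]}\t{assoc.microbe_ids[b]}\n")


def write_similarity_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    """TSV with an id header row and an id first column; loses no precision."""
    df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    # default float formatting is the shortest round-trip repr -> lossless
    df.to_csv(path, sep="\t", index_label=matrix.kind)


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # pandas' default float parser is fast but not correctly rounded;
    # round_trip keeps write->read bit-exact
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    kind = df.index.name
    if kind not in ("drug_weighted", "drug_plain", "microbe"):
        raise DataError(f"{path}: unrecognized similarity kind {kind!r}")
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise DataError(f"{path}: row/column id registries disagree")
    return SimilarityMatrix(ids=row_ids, values=df.to_numpy(dtype=float), kind=kind)


def write_drug_table(drugs: Iterable[DrugRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in drugs:
            fh.write(f"{d.id}\t{d.smiles}\n")


def write_microbe_fasta(microbes: Iterable[MicrobeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in microbes:
            fh.write(f">{m.id}\n{m.sequence}\n")
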