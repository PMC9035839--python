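"""Plain and atom-contribution-weighted Tanimoto similarity between drugs.

Drugs are encoded as 1,024-bit functional-class circular fingerprints.  The
weighted variant scores each atom of the comparison drug by how much removing
it changes the plain similarity to the reference drug, aggregates those atom
weights onto fingerprint bits through the bit->atom-environment map, and
evaluates a min/max Tanimoto over the weighted comparison fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .core_data import BipartiteAssociations, DrugRecord, SimilarityMatrix

RDLogger.DisableLog("rdApp.*")

DEFAULT_N_BITS = 1024
DEFAULT_RADIUS = 2


class FingerprintError(RuntimeError):
    pass


@dataclass
class Fingerprint:
    """Binary circular fingerprint plus its bit -> atom-environment map.

    ``bit_atom_map[q]`` is the set of atom indices covered by the
    substructure(s) that set bit q: for an environment of radius r rooted at
    atom a, the center atom plus all atoms within r bonds of it.
    """

    bits: np.ndarray
    bit_atom_map: dict[int, set[int]]
    n_atoms: int

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        for q, atoms in self.bit_atom_map.items():
            if not self.bits[q]:
                raise ValueError(f"bit_atom_map entry for off-bit {q}")
            for a in atoms:
                if not 0 <= a < self.n_atoms:
                    raise ValueError(f"bit {q}: atom index {a} out of range")

    @property
    def n_bits(self) -> int:
        return int(self.bits.shape[0])

    def on_bits(self) -> set[int]:
        return set(np.flatnonzero(self.bits).tolist())


def _feature_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(
        radius=radius,
        fpSize=n_bits,
        atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
    )


def _environment_atoms(mol: Chem.Mol, center: int, radius: int) -> set[int]:
    if radius == 0:
        return {center}
    bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
    atoms = {center}
    for bidx in bonds:
        bond = mol.GetBondWithIdx(bidx)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return atoms


def fingerprint_mol(
    mol: Chem.Mol, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS
) -> Fingerprint:
    """Fingerprint an RDKit molecule; empty molecules give the all-zero vector."""
    n_atoms = mol.GetNumAtoms()
    bits = np.zeros(n_bits, dtype=np.uint8)
    if n_atoms == 0:
        return Fingerprint(bits=bits, bit_atom_map={}, n_atoms=0)
    gen = _feature_generator(radius, n_bits)
    out = rdFingerprintGenerator.AdditionalOutput()
    out.AllocateBitInfoMap()
    fp = gen.GetFingerprint(mol, additionalOutput=out)
    bit_atom_map: dict[int, set[int]] = {}
    for q in fp.GetOnBits():
        bits[q] = 1
        atoms: set[int] = set()
        for center, env_radius in out.GetBitInfoMap()[q]:
            atoms |= _environment_atoms(mol, center, env_radius)
        bit_atom_map[q] = atoms
    return Fingerprint(bits=bits, bit_atom_map=bit_atom_map, n_atoms=n_atoms)


def fingerprint(
    drug: DrugRecord, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS
) -> Fingerprint:
    mol = Chem.MolFromSmiles(drug.smiles)
    if mol is None:
        raise FingerprintError(f"drug {drug.id!r}: SMILES does not parse")
    return fingerprint_mol(mol, radius=radius, n_bits=n_bits)


def tanimoto(fa: Fingerprint | np.ndarray, fb: Fingerprint | np.ndarray) -> float:
    """Tanimoto coefficient a.b / (a.a + b.b - a.b); 0 for two empty vectors."""
    a = fa.bits if isinstance(fa, Fingerprint) else np.asarray(fa)
    b = fb.bits if isinstance(fb, Fingerprint) else np.asarray(fb)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    a = a.astype(np.int64)
    b = b.astype(np.int64)
    ab = int(a @ b)
    denom = int(a @ a) + int(b @ b) - ab
    return ab / denom if denom else 0.0


@dataclass
class AtomWeightVector:
    """Per-atom contribution weights of a comparison drug against a reference."""

    weights: np.ndarray
    base_similarity: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size and self.weights.min() < 0:
            raise ValueError("atom weights must be nonnegative")


@dataclass
class BitWeightVector:
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size and self.weights.min() < 0:
            raise ValueError("bit weights must be nonnegative")


def _delete_atom(mol: Chem.Mol, atom_idx: int) -> Chem.Mol | None:
    """Remove one atom and return the largest fingerprintable fragment.

    Deletion can break sanitization (aromatic rings, valence); we fall back to
    lenient sanitization, and return None when nothing usable remains.
    """
    rw = Chem.RWMol(mol)
    rw.RemoveAtom(atom_idx)
    if rw.GetNumAtoms() == 0:
        return None
    frags = Chem.GetMolFrags(rw, asMols=True, sanitizeFrags=False)
    frag = max(frags, key=lambda f: f.GetNumAtoms())
    try:
        Chem.SanitizeMol(frag)
        return frag
    except Exception:
        pass
    try:
        frag.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(
            frag,
            sanitizeOps=Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
            | Chem.SanitizeFlags.SANITIZE_FINDRADICALS
            | Chem.SanitizeFlags.SANITIZE_SYMMRINGS,
            catchErrors=True,
        )
        return frag
    except Exception:
        return None


def atom_weights(
    reference: DrugRecord,
    comparison: DrugRecord,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> AtomWeightVector:
    """Score each atom of the comparison drug by leave-one-atom-out deltas.

    Atom k's weight is |S(ref, cmp) - S(ref, cmp minus atom k)|, where the
    reduced molecule is fingerprinted after deleting atom k and its bonds.
    """
    ref_mol = Chem.MolFromSmiles(reference.smiles)
    cmp_mol = Chem.MolFromSmiles(comparison.smiles)
    if ref_mol is None or cmp_mol is None:
        raise FingerprintError(
            f"invalid molecule in pair ({reference.id!r}, {comparison.id!r})"
        )
    ref_fp = fingerprint_mol(ref_mol, radius=radius, n_bits=n_bits)
    cmp_fp = fingerprint_mol(cmp_mol, radius=radius, n_bits=n_bits)
    base = tanimoto(ref_fp, cmp_fp)
    n_atoms = cmp_mol.GetNumAtoms()
    weights = np.zeros(n_atoms)
    for k in range(n_atoms):
        reduced = _delete_atom(cmp_mol, k)
        if reduced is None:
            s_reduced = 0.0
        else:
            try:
                s_reduced = tanimoto(
                    ref_fp, fingerprint_mol(reduced, radius=radius, n_bits=n_bits)
                )
            except Exception:
                s_reduced = 0.0
        weights[k] = abs(base - s_reduced)
    return AtomWeightVector(weights=weights, base_similarity=base)


def bit_weights(comparison_fp: Fingerprint, atom_w: AtomWeightVector) -> BitWeightVector:
    """Sum atom weights over each on-bit's atom environment; off-bits get 0."""
    if atom_w.weights.shape[0] != comparison_fp.n_atoms:
        raise ValueError(
            f"atom weight length {atom_w.weights.shape[0]} does not match "
            f"{comparison_fp.n_atoms} atoms"
        )
    w = np.zeros(comparison_fp.n_bits)
    for q, atoms in comparison_fp.bit_atom_map.items():
        # sorted iteration keeps float summation order deterministic
        w[q] = float(sum(atom_w.weights[a] for a in sorted(atoms)))
    return BitWeightVector(weights=w)


def weighted_tanimoto(
    reference_fp: Fingerprint, comparison_fp: Fingerprint, bit_w: BitWeightVector
) -> float:
    """Sum_q min(f_i, w_q f_j) / sum_q max(f_i, w_q f_j); 0 on zero denominator."""
    if reference_fp.n_bits != comparison_fp.n_bits or bit_w.weights.shape[0] != reference_fp.n_bits:
        raise ValueError("fingerprint / weight length mismatch")
    fi = reference_fp.bits.astype(float)
    wfj = bit_w.weights * comparison_fp.bits
    num = np.minimum(fi, wfj).sum()
    den = np.maximum(fi, wfj).sum()
    return float(num / den) if den > 0 else 0.0


def drug_similarity_matrix(
    drugs: list[DrugRecord],
    mode: str = "plain",
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> SimilarityMatrix:
    """Pairwise drug similarity.

    ``plain`` mode is the symmetric Tanimoto matrix with unit diagonal.
    ``weighted`` mode stores the directed matrix: entry [i, j] treats drug i
    as the reference and drug j as the comparison.
    """
    if not drugs:
        raise ValueError("need at least one drug")
    if mode not in ("plain", "weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = [d.id for d in drugs]
    fps = [fingerprint(d, radius=radius, n_bits=n_bits) for d in drugs]
    m = len(drugs)
    vals = np.zeros((m, m))
    if mode == "plain":
        for i in range(m):
            vals[i, i] = 1.0
            for j in range(i + 1, m):
                vals[i, j] = vals[j, i] = tanimoto(fps[i], fps[j])
        return SimilarityMatrix(ids=ids, values=vals, kind="drug_plain")
    for j in range(m):
        # atom weights depend only on (reference, comparison); one pass per
        # comparison drug j computes its deletions once per reference i
        for i in range(m):
            aw = atom_weights(drugs[i], drugs[j], radius=radius, n_bits=n_bits)
            bw = bit_weights(fps[j], aw)
            vals[i, j] = min(1.0, weighted_tanimoto(fps[i], fps[j], bw))
    return SimilarityMatrix(ids=ids, values=vals, kind="drug_weighted")


def fingerprint_similarity_matrix(
    ids: list[str], bit_matrix: np.ndarray
) -> SimilarityMatrix:
    """Plain Tanimoto matrix straight from stacked binary fingerprints."""
    m = bit_matrix.shape[0]
    if len(ids) != m:
        raise ValueError("id / fingerprint count mismatch")
    b = bit_matrix.astype(np.int64)
    inter = b @ b.T
    counts = np.diag(inter)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(ids=ids, values=vals, kind="drug_plain")


def build_drug_network(
    sim: SimilarityMatrix, assoc: BipartiteAssociations
) -> dict[tuple[int, int], float]:
    """Undirected drug network: edge (i, j) iff some microbe links both.

    Edge weight is the similarity; directed weighted similarity is
    symmetrized by averaging the two directions.  Pass training-fold
    associations during cross-validation so test labels cannot leak in.
    """
    if sim.ids != assoc.drug_ids:
        raise ValueError("similarity registry does not match association registry")
    vals = sim.symmetrized().values
    edges: dict[tuple[int, int], float] = {}
    for b in range(assoc.n_microbes):
        linked = sorted(assoc.drugs_of_microbe(b))
        for x in range(len(linked)):
            for y in range(x + 1, len(linked)):
                i, j = linked[x], linked[y]
                edges[(i, j)] = float(vals[i, j])
    return edges
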