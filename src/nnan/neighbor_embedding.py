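"""Sorted-neighbor key dictionaries and bidirectional pair embeddings.

Each node owns a key dictionary: all same-side nodes ordered by descending
similarity with the owner itself first.  The embedding of a pair (d_x, b_p)
concatenates a drug-side vector (similarities of d_x to drugs associated with
b_p, placed at their key positions in d_x's dictionary) with the mirror
microbe-side vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import BipartiteAssociations, SimilarityMatrix


@dataclass
class NeighborDictionary:
    """One node's ordered key list: self first, then descending similarity.

    Ties are broken by ascending registry index so the ordering is
    deterministic.  ``key_index[node]`` gives the key position (0-based) of a
    node in this dictionary.
    """

    owner: str
    keys: list[str]
    key_sims: np.ndarray
    key_index: dict[str, int]


@dataclass
class EmbeddingMatrix:
    """k pair embeddings stacked as a (k, g) matrix, g = L_d + L_b."""

    values: np.ndarray
    pairs: list[tuple[int, int]]
    drug_block_len: int
    microbe_block_len: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g = self.drug_block_len + self.microbe_block_len
        if self.values.shape != (len(self.pairs), g):
            raise ValueError(
                f"embedding shape {self.values.shape} inconsistent with "
                f"{len(self.pairs)} pairs and g={g}"
            )

    @property
    def g(self) -> int:
        return self.drug_block_len + self.microbe_block_len


def build_dictionaries(
    sim: SimilarityMatrix, L: int | None = None
) -> dict[str, NeighborDictionary]:
    """Key dictionaries for every node of a (symmetrized) similarity matrix.

    ``L`` truncates each dictionary to its first L keys (self included);
    None keeps the full side size.
    """
    vals = sim.symmetrized().values
    ids = sim.ids
    k = len(ids)
    dicts: dict[str, NeighborDictionary] = {}
    for i in range(k):
        others = [j for j in range(k) if j != i]
        # descending similarity, ties by ascending registry index
        others.sort(key=lambda j: (-vals[i, j], j))
        order = [i] + others
        if L is not None:
            order = order[:L]
        keys = [ids[j] for j in order]
        sims = np.array([1.0] + [vals[i, j] for j in order[1:]])
        dicts[ids[i]] = NeighborDictionary(
            owner=ids[i],
            keys=keys,
            key_sims=sims,
            key_index={ids[j]: pos for pos, j in enumerate(order)},
        )
    return dicts


def msdna(
    drug_id: str,
    microbe_index: int,
    drug_dicts: dict[str, NeighborDictionary],
    assoc_train: BipartiteAssociations,
    include_self: bool = False,
) -> np.ndarray:
    """Microbe-specific drug neighbor vector for the edge d_x -> b_p.

    Position i holds S_d(d_x, key_i) when the i-th key of d_x's dictionary is
    a drug associated with b_p in the training associations, else 0.  The
    owner drug is excluded from that neighbor set by default so the pair's
    own label never reaches its embedding; ``include_self=True`` restores the
    literal self-inclusive reading (key 1 then carries similarity 1 for
    training positives).
    """
    nd = drug_dicts[drug_id]
    neighbor_ids = {
        assoc_train.drug_ids[d] for d in assoc_train.drugs_of_microbe(microbe_index)
    }
    if not include_self:
        neighbor_ids.discard(drug_id)
    out = np.zeros(len(nd.keys))
    for node in neighbor_ids:
        pos = nd.key_index.get(node)
        if pos is not None:
            out[pos] = nd.key_sims[pos]
    return out


def dsmna(
    microbe_id: str,
    drug_index: int,
    microbe_dicts: dict[str, NeighborDictionary],
    assoc_train: BipartiteAssociations,
    include_self: bool = False,
) -> np.ndarray:
    """Drug-specific microbe neighbor vector for the edge b_p -> d_x (mirror)."""
    nd = microbe_dicts[microbe_id]
    neighbor_ids = {
        assoc_train.microbe_ids[b] for b in assoc_train.microbes_of_drug(drug_index)
    }
    if not include_self:
        neighbor_ids.discard(microbe_id)
    out = np.zeros(len(nd.keys))
    for node in neighbor_ids:
        pos = nd.key_index.get(node)
        if pos is not None:
            out[pos] = nd.key_sims[pos]
    return out


def embed_pairs(
    pairs: list[tuple[int, int]],
    drug_dicts: dict[str, NeighborDictionary],
    microbe_dicts: dict[str, NeighborDictionary],
    assoc_train: BipartiteAssociations,
    include_self: bool = False,
) -> EmbeddingMatrix:
    """Stack [msdna || dsmna] rows for (drug index, microbe index) pairs."""
    l_d = len(next(iter(drug_dicts.values())).keys) if drug_dicts else 0
    l_b = len(next(iter(microbe_dicts.values())).keys) if microbe_dicts else 0
    rows = np.zeros((len(pairs), l_d + l_b))
    for r, (d, b) in enumerate(pairs):
        rows[r, :l_d] = msdna(
            assoc_train.drug_ids[d], b, drug_dicts, assoc_train, include_self
        )
        rows[r, l_d:] = dsmna(
            assoc_train.microbe_ids[b], d, microbe_dicts, assoc_train, include_self
        )
    return EmbeddingMatrix(
        values=rows, pairs=list(pairs), drug_block_len=l_d, microbe_block_len=l_b
    )


def mask_top_l(E: EmbeddingMatrix, l: int) -> EmbeddingMatrix:
    """Zero out key positions beyond the first l within each directional block."""
    if l < 0:
        raise ValueError("l must be nonnegative")
    vals = E.values.copy()
    l_d = E.drug_block_len
    vals[:, min(l, l_d):l_d] = 0.0
    vals[:, l_d + min(l, E.microbe_block_len):] = 0.0
    return EmbeddingMatrix(
        values=vals,
        pairs=list(E.pairs),
        drug_block_len=l_d,
        microbe_block_len=E.microbe_block_len,
    )
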