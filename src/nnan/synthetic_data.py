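"""Desk-scale synthetic datasets with planted cluster structure.

Drugs come in fingerprint clusters (noisy copies of a prototype bit vector,
or members of a homologous SMILES family), microbes in sequence clusters
(point-mutated copies of a prototype), and each drug cluster preferentially
associates with a matched microbe cluster.  This reproduces the statistical
signal the predictor exploits: drugs sharing a microbe tend to be each
other's nearest neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core_data import BipartiteAssociations, DrugRecord, MicrobeRecord

# Homologous series of drug-like molecules; one family per cluster in
# smiles_library mode.  Members of a family are near neighbors under
# circular-fingerprint Tanimoto, unrelated families are distant.
SMILES_LIBRARY: dict[str, list[str]] = {
    "gallate_esters": [
        "COC(=O)c1cc(O)c(O)c(O)c1",
        "CCOC(=O)c1cc(O)c(O)c(O)c1",
        "CCCOC(=O)c1cc(O)c(O)c(O)c1",
        "CCCCOC(=O)c1cc(O)c(O)c(O)c1",
        "CCCCCOC(=O)c1cc(O)c(O)c(O)c1",
        "CCCCCCOC(=O)c1cc(O)c(O)c(O)c1",
        "CCCCCCCOC(=O)c1cc(O)c(O)c(O)c1",
        "CCCCCCCCOC(=O)c1cc(O)c(O)c(O)c1",
        "CCCCCCCCCOC(=O)c1cc(O)c(O)c(O)c1",
        "CCCCCCCCCCOC(=O)c1cc(O)c(O)c(O)c1",
    ],
    "n_alkanols": [
        "CCO", "CCCO", "CCCCO", "CCCCCO", "CCCCCCO",
        "CCCCCCCO", "CCCCCCCCO", "CCCCCCCCCO", "CCCCCCCCCCO", "CCCCCCCCCCCO",
    ],
    "para_halo_anilines": [
        "Nc1ccc(F)cc1", "Nc1ccc(Cl)cc1", "Nc1ccc(Br)cc1", "Nc1ccc(I)cc1",
        "CNc1ccc(F)cc1", "CNc1ccc(Cl)cc1", "CNc1ccc(Br)cc1", "CNc1ccc(I)cc1",
        "CCNc1ccc(Cl)cc1", "CCNc1ccc(Br)cc1",
    ],
    "alkyl_benzoates": [
        "COC(=O)c1ccccc1", "CCOC(=O)c1ccccc1", "CCCOC(=O)c1ccccc1",
        "CCCCOC(=O)c1ccccc1", "CCCCCOC(=O)c1ccccc1", "CCCCCCOC(=O)c1ccccc1",
        "CCCCCCCOC(=O)c1ccccc1", "CCCCCCCCOC(=O)c1ccccc1",
        "CCCCCCCCCOC(=O)c1ccccc1", "CCCCCCCCCCOC(=O)c1ccccc1",
    ],
    "fatty_acids": [
        "CCC(=O)O", "CCCC(=O)O", "CCCCC(=O)O", "CCCCCC(=O)O", "CCCCCCC(=O)O",
        "CCCCCCCC(=O)O", "CCCCCCCCC(=O)O", "CCCCCCCCCC(=O)O",
        "CCCCCCCCCCC(=O)O", "CCCCCCCCCCCC(=O)O",
    ],
    "pyridine_amides": [
        "NC(=O)c1ccccn1", "CNC(=O)c1ccccn1", "CCNC(=O)c1ccccn1",
        "CCCNC(=O)c1ccccn1", "NC(=O)c1cccnc1", "CNC(=O)c1cccnc1",
        "CCNC(=O)c1cccnc1", "CCCNC(=O)c1cccnc1", "NC(=O)c1ccncc1",
        "CNC(=O)c1ccncc1",
    ],
}

_BASES = np.array(list("ACGT"))


@dataclass
class SynthConfig:
    n_drug_clusters: int = 4
    drugs_per_cluster: int = 10
    n_microbe_clusters: int = 3
    microbes_per_cluster: int = 6
    fingerprint_mode: str = "random_bits"  # or "smiles_library"
    n_bits: int = 1024
    prototype_on_bits: int = 64
    bit_flip_rate: float = 0.02
    seq_len: int = 240
    seq_mutation_rate: float = 0.02
    assoc_within_prob: float = 0.8
    assoc_cross_prob: float = 0.02
    label_noise: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bit_flip_rate", "seq_mutation_rate", "assoc_within_prob",
                     "assoc_cross_prob", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.assoc_within_prob <= self.assoc_cross_prob:
            raise ValueError(
                "assoc_within_prob must exceed assoc_cross_prob for a "
                "learnable instance"
            )
        if self.fingerprint_mode not in ("random_bits", "smiles_library"):
            raise ValueError(f"unknown fingerprint_mode {self.fingerprint_mode!r}")
        if (
            self.fingerprint_mode == "smiles_library"
            and self.n_drug_clusters > len(SMILES_LIBRARY)
        ):
            raise ValueError(
                f"smiles_library mode supports at most {len(SMILES_LIBRARY)} clusters"
            )


@dataclass
class SynthDataset:
    drugs: list[DrugRecord] | None
    fingerprints: np.ndarray | None  # (m, n_bits) binary, random_bits mode
    microbes: list[MicrobeRecord]
    assoc: BipartiteAssociations
    drug_clusters: list[int]
    microbe_clusters: list[int]
    config: SynthConfig

    @property
    def drug_ids(self) -> list[str]:
        return self.assoc.drug_ids

    @property
    def microbe_ids(self) -> list[str]:
        return self.assoc.microbe_ids


def _mutate_sequence(proto: np.ndarray, rate: float, rng: np.random.Generator) -> str:
    seq = proto.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for pos in hits:
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    return "".join(seq)


def generate(config: SynthConfig) -> SynthDataset:
    """Generate a planted-cluster dataset, bit-reproducible from the config."""
    rng = np.random.default_rng(config.seed)
    m = config.n_drug_clusters * config.drugs_per_cluster
    n = config.n_microbe_clusters * config.microbes_per_cluster
    drug_ids = [f"D{i:03d}" for i in range(m)]
    microbe_ids = [f"M{i:03d}" for i in range(n)]
    drug_clusters = [i // config.drugs_per_cluster for i in range(m)]
    microbe_clusters = [i // config.microbes_per_cluster for i in range(n)]

    drugs: list[DrugRecord] | None = None
    fingerprints: np.ndarray | None = None
    if config.fingerprint_mode == "random_bits":
        fingerprints = np.zeros((m, config.n_bits), dtype=np.uint8)
        for c in range(config.n_drug_clusters):
            proto = np.zeros(config.n_bits, dtype=np.uint8)
            on = rng.choice(config.n_bits, size=config.prototype_on_bits, replace=False)
            proto[on] = 1
            for j in range(config.drugs_per_cluster):
                flips = rng.random(config.n_bits) < config.bit_flip_rate
                fingerprints[c * config.drugs_per_cluster + j] = proto ^ flips
    else:
        families = list(SMILES_LIBRARY.values())
        order = rng.permutation(len(families))
        drugs = []
        for c in range(config.n_drug_clusters):
            family = families[order[c]]
            for j in range(config.drugs_per_cluster):
                idx = c * config.drugs_per_cluster + j
                drugs.append(DrugRecord(id=drug_ids[idx], smiles=family[j % len(family)]))

    microbes: list[MicrobeRecord] = []
    for c in range(config.n_microbe_clusters):
        proto = _BASES[rng.integers(4, size=config.seq_len)]
        for j in range(config.microbes_per_cluster):
            idx = c * config.microbes_per_cluster + j
            microbes.append(
                MicrobeRecord(
                    id=microbe_ids[idx],
                    sequence=_mutate_sequence(proto, config.seq_mutation_rate, rng),
                )
            )

    edges: set[tuple[int, int]] = set()
    for d in range(m):
        for b in range(n):
            matched = (
                drug_clusters[d] % config.n_microbe_clusters == microbe_clusters[b]
            )
            p = config.assoc_within_prob if matched else config.assoc_cross_prob
            if rng.random() < p:
                edges.add((d, b))
    if config.label_noise > 0:
        for d in range(m):
            for b in range(n):
                if rng.random() < config.label_noise:
                    edges.symmetric_difference_update({(d, b)})

    assoc = BipartiteAssociations(
        drug_ids=drug_ids, microbe_ids=microbe_ids, edges=edges
    )
    return SynthDataset(
        drugs=drugs,
        fingerprints=fingerprints,
        microbes=microbes,
        assoc=assoc,
        drug_clusters=drug_clusters,
        microbe_clusters=microbe_clusters,
        config=config,
    )


def expected_edge_count(config: SynthConfig) -> float:
    """Closed-form expectation of |E| under the generator, noise included."""
    m = config.n_drug_clusters * config.drugs_per_cluster
    n = config.n_microbe_clusters * config.microbes_per_cluster
    matched = 0
    for dc in range(config.n_drug_clusters):
        for mc in range(config.n_microbe_clusters):
            if dc % config.n_microbe_clusters == mc:
                matched += config.drugs_per_cluster * config.microbes_per_cluster
    unmatched = m * n - matched
    e_base = matched * config.assoc_within_prob + unmatched * config.assoc_cross_prob
    # each pair flips with prob label_noise
    p_within = config.assoc_within_prob
    p_cross = config.assoc_cross_prob
    ln = config.label_noise
    e = matched * (p_within * (1 - ln) + (1 - p_within) * ln)
    e += unmatched * (p_cross * (1 - ln) + (1 - p_cross) * ln)
    del e_base
    return e


def worked_toy() -> SynthDataset:
    """Frozen 5-drug / 3-microbe instance with hand-enumerable similarities.

    No randomness is involved: the drugs are five small molecules, the
    microbes three short sequences, and the association edges are fixed.
    Used across the test suite as the cross-module oracle fixture.
    """
    drugs = [
        DrugRecord("D0", "CCO"),          # ethanol
        DrugRecord("D1", "CCCO"),         # 1-propanol
        DrugRecord("D2", "CCN"),          # ethylamine
        DrugRecord("D3", "c1ccccc1"),     # benzene
        DrugRecord("D4", "CC(=O)O"),      # acetic acid
    ]
    microbes = [
        MicrobeRecord("M0", "ACGTACGT"),
        MicrobeRecord("M1", "ACGTTCGT"),
        MicrobeRecord("M2", "TTTTCCCC"),
    ]
    edges = {(0, 0), (1, 0), (2, 0), (1, 1), (3, 1), (4, 2), (0, 2)}
    assoc = BipartiteAssociations(
        drug_ids=[d.id for d in drugs],
        microbe_ids=[m.id for m in microbes],
        edges=edges,
    )
    config = SynthConfig(
        n_drug_clusters=1,
        drugs_per_cluster=5,
        n_microbe_clusters=1,
        microbes_per_cluster=3,
        fingerprint_mode="smiles_library",
        seq_len=8,
        assoc_within_prob=0.5,
        assoc_cross_prob=0.0,
        label_noise=0.0,
        seed=0,
    )
    return SynthDataset(
        drugs=drugs,
        fingerprints=None,
        microbes=microbes,
        assoc=assoc,
        drug_clusters=[0] * 5,
        microbe_clusters=[0] * 3,
        config=config,
    )
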