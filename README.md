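# nnan

Nearest-neighbor attention network for drug–microbe association prediction.

Given a table of drugs (SMILES), a FASTA of microbe sequences, and a list of
known drug–microbe associations, `nnan` predicts new associations by:

1. **Drug similarity** — 1,024-bit functional-class circular fingerprints
   (RDKit) compared by the Tanimoto coefficient, plus an atom-contribution
   *weighted* variant: each atom of a comparison drug is scored by how much
   deleting it changes the similarity to the reference drug, atom weights are
   aggregated onto fingerprint bits, and a min/max weighted Tanimoto is
   evaluated (`nnan.drug_similarity`).
2. **Microbe similarity** — exact Smith–Waterman local alignment
   (match +1 / mismatch −1 / linear gap 2), normalized by the geometric mean
   of the self-alignment scores (`nnan.microbe_similarity`).
3. **Neighbor embeddings** — each node owns a key dictionary of same-side
   nodes sorted by descending similarity (self first). A pair (drug,
   microbe) is embedded as the concatenation of two vectors: similarities of
   the drug to the drugs associated with the microbe, placed at their key
   positions, and the mirror on the microbe side (`nnan.neighbor_embedding`).
4. **Attention + predictor** — a bank of per-feature scalar subnetworks
   gates every embedding entry into (0, 1); the gated matrix feeds a small
   one-hidden-layer classifier. Both are trained jointly with binary
   cross-entropy + L2 by plain gradient descent, implemented in NumPy with
   hand-derived gradients for full single-CPU reproducibility
   (`nnan.attention_predictor`).
5. **Evaluation** — 5-fold cross-validation in the positive-unlabeled
   setting with all per-round structure rebuilt from training positives only
   (no label leakage), rank-based AUROC, step-integrated AUPRC, embedding /
   attention interpretability profiles, top-*l* feature experiments,
   similarity-neighbor checks and candidate ranking (`nnan.evaluation`).
6. **Synthetic data** — planted-cluster generators (random fingerprint
   clusters or homologous SMILES families, mutated sequence clusters,
   block-structured associations) so the whole pipeline is testable offline
   (`nnan.synthetic_data`).

## CLI

```bash
# generate a synthetic dataset
nnan synth --out data/ --seed 0

# similarity matrices
nnan drug-sim --drugs data/drugs.tsv --mode weighted --out Sd.tsv
nnan microbe-sim --fasta data/microbes.fa --out Sb.tsv

# pair embeddings (npz container)
nnan embed --sd Sd.tsv --sb Sb.tsv --assoc data/assoc.tsv --out E.npz

# 5-fold cross-validation with a JSON report
nnan cv --drugs data/drugs.tsv --microbes data/microbes.fa \
        --assoc data/assoc.tsv --report report.json

# rank candidate drugs for one microbe / inspect neighbor structure
nnan rank --microbe M000 --drugs data/drugs.tsv --microbes data/microbes.fa \
          --assoc data/assoc.tsv --out ranked.tsv
nnan neighbors --drug D000 --microbe M000 --drugs data/drugs.tsv \
               --microbes data/microbes.fa --assoc data/assoc.tsv
nnan explain --drugs data/drugs.tsv --microbes data/microbes.fa \
             --assoc data/assoc.tsv --out profiles.tsv
```

Training hyperparameters (YAML passed via `--config`) default to constant
learning rate 0.9, batch size 3000, 2000 epochs, L2 coefficient 2e-4.

## Reproducing published-scale benchmarks

The benchmark databases used in the original study are not redistributed
here. To run on real data, prepare `drugs.tsv` (id, SMILES), `microbes.fa`
and `assoc.tsv` (drug id, microbe id) and use `nnan cv`. Genome-scale
sequences are truncated to a centered 50 kb window by default
(`--max-seq-len`) to bound the quadratic alignment cost.
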