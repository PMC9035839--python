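"""Cross-validation, ranking metrics, and interpretability diagnostics.

Evaluation follows a positive-unlabeled protocol: known associations are
positives and (by default all) unlabeled pairs serve as negatives.  Positives
and negatives are shuffled and split into five folds; each round trains on
four folds and scores the fifth.  Crucially, every per-round structure
(neighbor sets, network edges, embeddings) is rebuilt from that round's
training positives only, so test labels cannot leak into features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .attention_predictor import Model, TrainConfig, TrainState, train
from .core_data import BipartiteAssociations, SimilarityMatrix
from .neighbor_embedding import (
    EmbeddingMatrix,
    build_dictionaries,
    embed_pairs,
    mask_top_l,
)

Pair = tuple[int, int]


@dataclass
class CVPlan:
    """Disjoint positive and negative fold partitions plus the seed used."""

    positive_folds: list[list[Pair]]
    negative_folds: list[list[Pair]]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.positive_folds)

    def round_inputs(
        self, fold: int
    ) -> tuple[list[Pair], np.ndarray, list[Pair], np.ndarray]:
        """(train_pairs, train_labels, test_pairs, test_labels) for one round."""
        train_pairs: list[Pair] = []
        train_labels: list[int] = []
        for f in range(self.n_folds):
            if f == fold:
                continue
            train_pairs += self.positive_folds[f] + self.negative_folds[f]
            train_labels += [1] * len(self.positive_folds[f])
            train_labels += [0] * len(self.negative_folds[f])
        test_pairs = self.positive_folds[fold] + self.negative_folds[fold]
        test_labels = [1] * len(self.positive_folds[fold]) + [0] * len(
            self.negative_folds[fold]
        )
        return (
            train_pairs,
            np.array(train_labels, dtype=float),
            test_pairs,
            np.array(test_labels, dtype=float),
        )


def make_cv_plan(
    assoc: BipartiteAssociations,
    negative_ratio: float | str = "all",
    seed: int = 0,
    n_folds: int = 5,
) -> CVPlan:
    """Shuffle positives and sampled negatives, split each into near-equal folds.

    ``negative_ratio='all'`` keeps every unlabeled pair as a negative (the
    published protocol); a float r subsamples r * |positives| negatives.
    """
    positives = sorted(assoc.edges)
    if len(positives) < n_folds:
        raise ValueError(f"need at least {n_folds} positives, got {len(positives)}")
    rng = np.random.default_rng(seed)
    positives = [positives[i] for i in rng.permutation(len(positives))]
    negatives = assoc.negatives()
    negatives = [negatives[i] for i in rng.permutation(len(negatives))]
    if negative_ratio != "all":
        n_keep = min(len(negatives), int(round(float(negative_ratio) * len(positives))))
        negatives = negatives[:n_keep]
    pos_folds = [list(f) for f in np.array_split(np.arange(len(positives)), n_folds)]
    neg_folds = [list(f) for f in np.array_split(np.arange(len(negatives)), n_folds)]
    return CVPlan(
        positive_folds=[[positives[i] for i in f] for f in pos_folds],
        negative_folds=[[negatives[i] for i in f] for f in neg_folds],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUROC with tied scores averaged (Mann-Whitney statistic)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under precision-recall by step-wise integration (average precision).

    Sum over descending score thresholds of precision * recall increment;
    tied scores enter as one threshold group.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0 or int((labels == 0).sum()) == 0:
        raise ValueError("AUPRC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group boundaries where the threshold changes
    boundary = np.flatnonzero(np.diff(s)) + 1
    ends = np.concatenate([boundary, [len(s)]])
    tp = np.cumsum(y)[ends - 1]
    pred_pos = ends
    precision = tp / pred_pos
    recall = tp / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * precision))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    train: TrainConfig = field(default_factory=TrainConfig)
    negative_ratio: float | str = "all"
    n_folds: int = 5
    seed: int = 0
    include_self: bool = False
    top_l: int | None = None


@dataclass
class RoundResult:
    auroc: float
    auprc: float
    model: Model
    state: TrainState
    test_pairs: list[Pair]
    test_scores: np.ndarray
    test_labels: np.ndarray


@dataclass
class MetricReport:
    fold_auroc: list[float]
    fold_auprc: list[float]
    mean_auroc: float
    mean_auprc: float
    pooled_auroc: float
    pooled_auprc: float
    loss_traces: list[list[float]]
    seed: int
    config: dict

    def to_dict(self) -> dict:
        return asdict(self)


def run_round(
    drug_sim: SimilarityMatrix,
    microbe_sim: SimilarityMatrix,
    assoc_table: BipartiteAssociations,
    train_pairs: list[Pair],
    train_labels: np.ndarray,
    test_pairs: list[Pair],
    test_labels: np.ndarray,
    config: PipelineConfig,
    fold: int = 0,
) -> RoundResult:
    """Train and score one CV round.

    ``assoc_table`` supplies only the id registries; all graph structure is
    rebuilt from the training positives in ``train_pairs``, so edges present
    in the table but absent from the training folds (e.g., this round's test
    positives) have no influence.
    """
    train_pos = {p for p, y in zip(train_pairs, train_labels) if y == 1}
    assoc_train = BipartiteAssociations(
        drug_ids=list(assoc_table.drug_ids),
        microbe_ids=list(assoc_table.microbe_ids),
        edges=train_pos,
    )
    drug_dicts = build_dictionaries(drug_sim)
    microbe_dicts = build_dictionaries(microbe_sim)
    E_train = embed_pairs(
        train_pairs, drug_dicts, microbe_dicts, assoc_train, config.include_self
    )
    E_test = embed_pairs(
        test_pairs, drug_dicts, microbe_dicts, assoc_train, config.include_self
    )
    if config.top_l is not None:
        E_train = mask_top_l(E_train, config.top_l)
        E_test = mask_top_l(E_test, config.top_l)
    train_cfg = TrainConfig(**{**asdict(config.train), "seed": config.train.seed + fold})
    model, state = train(E_train, train_labels, train_cfg)
    scores = model.score(E_test)
    return RoundResult(
        auroc=auroc(scores, test_labels),
        auprc=auprc(scores, test_labels),
        model=model,
        state=state,
        test_pairs=list(test_pairs),
        test_scores=scores,
        test_labels=np.asarray(test_labels, dtype=float),
    )


def run_cv(
    drug_sim: SimilarityMatrix,
    microbe_sim: SimilarityMatrix,
    assoc: BipartiteAssociations,
    config: PipelineConfig = PipelineConfig(),
    plan: CVPlan | None = None,
) -> MetricReport:
    """Full k-fold cross-validation; reports per-fold, mean and pooled metrics."""
    if plan is None:
        plan = make_cv_plan(assoc, config.negative_ratio, config.seed, config.n_folds)
    fold_auroc: list[float] = []
    fold_auprc: list[float] = []
    traces: list[list[float]] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for fold in range(plan.n_folds):
        tr_p, tr_y, te_p, te_y = plan.round_inputs(fold)
        res = run_round(
            drug_sim, microbe_sim, assoc, tr_p, tr_y, te_p, te_y, config, fold
        )
        fold_auroc.append(res.auroc)
        fold_auprc.append(res.auprc)
        traces.append(res.state.loss_trace)
        pooled_scores.append(res.test_scores)
        pooled_labels.append(res.test_labels)
    all_scores = np.concatenate(pooled_scores)
    all_labels = np.concatenate(pooled_labels)
    cfg = asdict(config.train)
    cfg.update(
        negative_ratio=config.negative_ratio,
        n_folds=config.n_folds,
        include_self=config.include_self,
        top_l=config.top_l,
    )
    return MetricReport(
        fold_auroc=fold_auroc,
        fold_auprc=fold_auprc,
        mean_auroc=float(np.mean(fold_auroc)),
        mean_auprc=float(np.mean(fold_auprc)),
        pooled_auroc=auroc(all_scores, all_labels),
        pooled_auprc=auprc(all_scores, all_labels),
        loss_traces=traces,
        seed=config.seed,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# interpretability diagnostics
# ---------------------------------------------------------------------------


@dataclass
class ImportanceProfile:
    feature_importance: np.ndarray | None
    positive_profile: np.ndarray
    unlabeled_profile: np.ndarray


def embedding_profiles(
    E: EmbeddingMatrix | np.ndarray, labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-key column means of the embedding matrix, split by label."""
    X = E.values if isinstance(E, EmbeddingMatrix) else np.asarray(E, dtype=float)
    labels = np.asarray(labels)
    if not (labels == 1).any() or not (labels == 0).any():
        raise ValueError("need at least one row of each class")
    return X[labels == 1].mean(axis=0), X[labels == 0].mean(axis=0)


def feature_importance(M: np.ndarray) -> np.ndarray:
    """Global importance of each feature dimension: column means of M."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be 2-D")
    return M.mean(axis=0)


def top_l_experiment(
    l_values: Sequence[int],
    drug_sim: SimilarityMatrix,
    microbe_sim: SimilarityMatrix,
    assoc: BipartiteAssociations,
    config: PipelineConfig = PipelineConfig(),
) -> list[tuple[int, float, float]]:
    """Retrain and evaluate with only the first l keys per directional block.

    Every l reuses the same CV plan so the curves are comparable; l larger
    than a block is clamped to the block length.
    """
    import logging

    plan = make_cv_plan(assoc, config.negative_ratio, config.seed, config.n_folds)
    max_block = max(assoc.n_drugs, assoc.n_microbes)
    curve = []
    for l in l_values:
        if l > max_block:
            logging.getLogger("nnan").warning(
                "top-l value %d exceeds block length; clamped to %d", l, max_block
            )
            l = max_block
        cfg = PipelineConfig(
            train=config.train,
            negative_ratio=config.negative_ratio,
            n_folds=config.n_folds,
            seed=config.seed,
            include_self=config.include_self,
            top_l=l,
        )
        report = run_cv(drug_sim, microbe_sim, assoc, cfg, plan=plan)
        curve.append((l, report.mean_auroc, report.mean_auprc))
    return curve


def neighbor_check(
    drug_id: str,
    microbe_id: str,
    top_k: int,
    sim: SimilarityMatrix,
    assoc: BipartiteAssociations,
) -> tuple[list[tuple[int, str, float, bool]], int]:
    """Rank all other drugs by similarity to a reference drug and flag which
    associate with the given microbe; returns the table and the flagged count
    among the top_k."""
    d_ref = sim.index_of(drug_id)
    if microbe_id not in assoc.microbe_ids:
        raise KeyError(f"unknown microbe id {microbe_id!r}")
    b = assoc.microbe_ids.index(microbe_id)
    vals = sim.symmetrized().values
    linked = assoc.drugs_of_microbe(b)
    others = [j for j in range(len(sim.ids)) if j != d_ref]
    others.sort(key=lambda j: (-vals[d_ref, j], j))
    table = [
        (rank + 1, sim.ids[j], float(vals[d_ref, j]), j in linked)
        for rank, j in enumerate(others)
    ]
    flagged = sum(1 for row in table[:top_k] if row[3])
    return table, flagged


def rank_candidates(
    microbe_id: str,
    model: Model,
    drug_sim: SimilarityMatrix,
    microbe_sim: SimilarityMatrix,
    assoc: BipartiteAssociations,
    exclude_known: bool = True,
    include_self: bool = False,
) -> list[tuple[str, float]]:
    """Score every drug against one microbe and rank by descending probability.

    Known positives are excluded by default; ties break by ascending drug id.
    """
    if microbe_id not in assoc.microbe_ids:
        raise KeyError(f"unknown microbe id {microbe_id!r}")
    b = assoc.microbe_ids.index(microbe_id)
    known = assoc.drugs_of_microbe(b)
    drug_dicts = build_dictionaries(drug_sim)
    microbe_dicts = build_dictionaries(microbe_sim)
    candidates = [
        d for d in range(assoc.n_drugs) if not (exclude_known and d in known)
    ]
    pairs = [(d, b) for d in candidates]
    E = embed_pairs(pairs, drug_dicts, microbe_dicts, assoc, include_self)
    scores = model.score(E)
    ranked = sorted(
        zip(candidates, scores), key=lambda t: (-t[1], assoc.drug_ids[t[0]])
    )
    return [(assoc.drug_ids[d], float(s)) for d, s in ranked]
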