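"""Normalized local-alignment similarity between microbe sequences.

The score of the best local alignment (match +1, mismatch -1, linear gap
penalty 2 per gapped position) is normalized by the geometric mean of the
two self-alignment scores, giving a similarity in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import BipartiteAssociations, MicrobeRecord, SimilarityMatrix

# N scores as a mismatch against every base, including another N.
_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class AlignmentScoreParams:
    match: int = 1
    mismatch: int = -1
    gap: int = 2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0:
            raise ValueError("mismatch score must be <= 0")
        if self.gap <= 0:
            raise ValueError("gap penalty must be positive")


@dataclass(frozen=True)
class LocalAlignmentResult:
    score: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("local alignment score cannot be negative")


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODES[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"invalid sequence character {e.args[0]!r}") from None


def smith_waterman(
    a: str, b: str, params: AlignmentScoreParams = AlignmentScoreParams()
) -> LocalAlignmentResult:
    """Best local alignment score under linear gap scoring.

    Standard DP with a zero first row/column:
    H[i,j] = max(H[i-1,j-1] + score(a_i, b_j), H[i-1,j] - gap, H[i,j-1] - gap, 0),
    returning the maximum over all cells.  Rows are vectorized; the in-row
    left-gap dependency is resolved with a running-max trick (for linear gaps,
    chained left-gap moves reduce to max_t (tmp[t] + gap*t) - gap*j).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea, eb = _encode(a), _encode(b)
    n, m = len(ea), len(eb)
    match, mismatch, gap = params.match, params.mismatch, params.gap
    # substitution scores against b for each code; N (code 4) never matches
    sub = np.full((5, m), mismatch, dtype=np.int64)
    for code in range(4):
        sub[code, eb == code] = match
    offsets = gap * np.arange(m, dtype=np.int64)
    prev = np.zeros(m + 1, dtype=np.int64)
    best = 0
    neg_inf = np.int64(np.iinfo(np.int64).min // 4)
    for i in range(n):
        diag = prev[:-1] + sub[ea[i]]
        tmp = np.maximum(np.maximum(diag, prev[1:] - gap), 0)
        shifted = np.empty(m, dtype=np.int64)
        shifted[0] = neg_inf
        if m > 1:
            np.maximum.accumulate(tmp[:-1] + offsets[:-1], out=shifted[1:])
        row = np.maximum(tmp, shifted - offsets)
        best = max(best, int(row.max(initial=0)))
        prev[1:] = row
    return LocalAlignmentResult(score=best)


def microbe_similarity(
    a: MicrobeRecord,
    b: MicrobeRecord,
    params: AlignmentScoreParams = AlignmentScoreParams(),
) -> float:
    """sw(A,B) / sqrt(sw(A,A) * sw(B,B)).

    Self-scores are computed, not assumed equal to sequence length, so
    non-default scoring parameters (and N-containing sequences) stay correct.
    """
    saa = smith_waterman(a.sequence, a.sequence, params).score
    sbb = smith_waterman(b.sequence, b.sequence, params).score
    if saa == 0 or sbb == 0:
        return 1.0 if a.sequence == b.sequence else 0.0
    sab = smith_waterman(a.sequence, b.sequence, params).score
    return float(sab / np.sqrt(saa * sbb))


def microbe_similarity_matrix(
    microbes: list[MicrobeRecord],
    params: AlignmentScoreParams = AlignmentScoreParams(),
    max_seq_len: int | None = 50_000,
) -> SimilarityMatrix:
    """Symmetric n x n similarity matrix with unit diagonal.

    Sequences longer than ``max_seq_len`` are truncated to a centered
    subsequence to bound the quadratic DP cost on genome-scale inputs.
    """
    if not microbes:
        raise ValueError("need at least one microbe")
    recs = microbes
    if max_seq_len is not None:
        recs = []
        for rec in microbes:
            if len(rec.sequence) > max_seq_len:
                start = (len(rec.sequence) - max_seq_len) // 2
                recs.append(
                    MicrobeRecord(rec.id, rec.sequence[start : start + max_seq_len])
                )
            else:
                recs.append(rec)
    n = len(recs)
    self_scores = [
        smith_waterman(r.sequence, r.sequence, params).score for r in recs
    ]
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if self_scores[i] == 0 or self_scores[j] == 0:
                s = 1.0 if recs[i].sequence == recs[j].sequence else 0.0
            else:
                sab = smith_waterman(recs[i].sequence, recs[j].sequence, params).score
                s = float(sab / np.sqrt(self_scores[i] * self_scores[j]))
            vals[i, j] = vals[j, i] = min(s, 1.0)
    return SimilarityMatrix(ids=[r.id for r in recs], values=vals, kind="microbe")


def build_microbe_network(
    sim: SimilarityMatrix, assoc: BipartiteAssociations
) -> dict[tuple[int, int], float]:
    """Undirected microbe network: edge (p, q) iff some drug links both."""
    if sim.ids != assoc.microbe_ids:
        raise ValueError("similarity registry does not match association registry")
    edges: dict[tuple[int, int], float] = {}
    for d in range(assoc.n_drugs):
        linked = sorted(assoc.microbes_of_drug(d))
        for x in range(len(linked)):
            for y in range(x + 1, len(linked)):
                i, j = linked[x], linked[y]
                edges[(i, j)] = float(sim.values[i, j])
    return edges
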