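"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (enumeration, scalar loops, set
arithmetic) and shares no code path with the package implementation.
"""

from itertools import combinations
import math


def tanimoto_sets(a_bits: set[int], b_bits: set[int]) -> float:
    """|A n B| / |A u B| on on-bit sets; 0 when both are empty."""
    union = a_bits | b_bits
    if not union:
        return 0.0
    return len(a_bits & b_bits) / len(union)


def local_alignment_enumeration(a: str, b: str, match=1, mismatch=-1, gap=2) -> int:
    """Best local alignment score by exhaustive enumeration.

    A local alignment is a monotone sequence of aligned columns (trimming
    leading/trailing gaps never lowers the score); interior skipped positions
    each cost the gap penalty.  Enumerates every pair of equal-size monotone
    position subsets, so only valid for short sequences.
    """
    n, m = len(a), len(b)
    best = 0
    for L in range(1, min(n, m) + 1):
        for ia in combinations(range(n), L):
            for ib in combinations(range(m), L):
                score = 0
                for k in range(L):
                    ca, cb = a[ia[k]], b[ib[k]]
                    score += match if (ca == cb and ca != "N") else mismatch
                for k in range(1, L):
                    score -= gap * (ia[k] - ia[k - 1] - 1)
                    score -= gap * (ib[k] - ib[k - 1] - 1)
                best = max(best, score)
    return best


def auroc_pair_counting(scores, labels) -> float:
    """Concordant-pair count (ties half) over n_pos * n_neg."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    c = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                c += 1.0
            elif p == q:
                c += 0.5
    return c / (len(pos) * len(neg))


def auprc_step_integration(scores, labels) -> float:
    """Step-wise precision-recall integration by a scalar threshold loop."""
    thresholds = sorted(set(scores), reverse=True)
    n_pos = sum(1 for y in labels if y == 1)
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        pred_pos = sum(1 for s in scores if s >= t)
        precision = tp / pred_pos
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def bce_scalar_loop(P, Y, eps=1e-7) -> float:
    total = 0.0
    for p, y in zip(P, Y):
        p = min(max(p, eps), 1.0 - eps)
        total += y * math.log(p) + (1.0 - y) * math.log(1.0 - p)
    return -total / len(P)
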