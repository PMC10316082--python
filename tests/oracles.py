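"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths (and vectorization) of the package:
plain Python loops, itertools enumeration, and the textbook formulas.
"""

import itertools
import math


def brute_force_pairwise_median(x1, x2):
    """All M*N ratios under the zero policy, median by explicit sort."""
    ratios = []
    for a in x1:
        for b in x2:
            if a == 0 and b == 0:
                continue
            if b == 0:
                ratios.append(math.inf)
            elif a == 0:
                ratios.append(0.0)
            else:
                ratios.append(a / b)
    n = len(ratios)
    if n == 0:
        return math.nan, 0
    ratios.sort()
    if n % 2 == 1:
        return ratios[n // 2], n
    lo, hi = ratios[n // 2 - 1], ratios[n // 2]
    if math.isinf(hi):
        return math.inf, n
    return (lo + hi) / 2.0, n


def rank_sum_u(x1, x2):
    """U1, U2 from midrank sums, textbook definition."""
    pooled = sorted(list(x1) + list(x2))

    def midrank(v):
        lo = pooled.index(v)
        hi = len(pooled) - 1 - pooled[::-1].index(v)
        return (lo + hi) / 2.0 + 1.0

    n1, n2 = len(x1), len(x2)
    r1 = sum(midrank(v) for v in x1)
    r2 = sum(midrank(v) for v in x2)
    u1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    u2 = n1 * n2 + n2 * (n2 + 1) / 2.0 - r2
    return u1, u2


def exact_wilcoxon_p(x1, x2):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Tie-free inputs only. Enumerates every way the n1 group-1 ranks can fall
    among the n1+n2 positions, builds the exact null distribution of U1, and
    sums P(U1 <= u_min) + P(U1 >= n1*n2 - u_min).
    """
    n1, n2 = len(x1), len(x2)
    u1, u2 = rank_sum_u(x1, x2)
    u_min = min(u1, u2)
    mn = n1 * n2
    total = 0
    extreme = 0
    for pos in itertools.combinations(range(n1 + n2), n1):
        r1 = sum(pos) + n1  # ranks are positions + 1
        u = mn + n1 * (n1 + 1) / 2.0 - r1
        total += 1
        if u <= u_min or u >= mn - u_min:
            extreme += 1
    return extreme / total


def brute_force_pr_points(scores, labels):
    """(threshold, precision, recall, tp) for every distinct score, by
    explicit confusion-matrix counting."""
    n_true = sum(labels.values())
    points = []
    for t in sorted(set(scores.values()), reverse=True):
        tp = sum(1 for k, s in scores.items() if s >= t and labels[k])
        fp = sum(1 for k, s in scores.items() if s >= t and not labels[k])
        points.append((t, tp / (tp + fp), tp / n_true, tp))
    return points
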