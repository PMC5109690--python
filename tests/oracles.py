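"""Independent brute-force oracles used to verify the package's statistics.

These deliberately avoid the code paths they check: Fisher p-values come
from exact hypergeometric enumeration with rational arithmetic, rank-sum
p-values from full enumeration of rank assignments, ROC AUC from the
pairwise Mann-Whitney comparison count, and information gain from direct
entropy arithmetic on discrete groups.
"""

from fractions import Fraction
from itertools import combinations
from math import comb, log2


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration:
    sum of P(table) over all tables with the observed margins whose
    probability does not exceed the observed table's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = pmf(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = pmf(x)
        if p <= p_obs:
            total += p
    return float(total)


def ranksum_exact_oracle(xs, ys) -> float:
    """Two-sided rank-sum p by enumerating every assignment of the pooled
    observations to the first sample (midranks for ties)."""
    nx = len(xs)
    pooled = sorted(list(xs) + list(ys))
    # midranks
    ranks = {}
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        mid = (i + 1 + j) / 2.0
        ranks[pooled[i]] = mid
        i = j
    rank_list = [ranks[v] for v in pooled]

    def u_of(idx):
        return sum(rank_list[i] for i in idx) - nx * (nx + 1) / 2.0

    mu = nx * len(ys) / 2.0
    # observed U from the actual sample membership
    obs_ranks = sorted(ranks[v] for v in xs)
    u_obs = sum(obs_ranks) - nx * (nx + 1) / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), nx):
        total += 1
        if abs(u_of(idx) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def roc_auc_pairwise_oracle(scores, labels) -> float:
    """ROC AUC as the normalized Mann-Whitney U: the fraction of
    (positive, negative) pairs ranked correctly, ties counting half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def entropy_oracle(labels) -> float:
    n = len(labels)
    h = 0.0
    for c in set(labels):
        p = sum(1 for l in labels if l == c) / n
        h -= p * log2(p)
    return h


def information_gain_oracle(feature_values, labels) -> float:
    """IG by direct entropy arithmetic, conditioning on the discrete feature
    value (coincides with binary-threshold discretization for binary
    features)."""
    n = len(labels)
    h_root = entropy_oracle(labels)
    cond = 0.0
    for v in set(feature_values):
        sub = [l for f, l in zip(feature_values, labels) if f == v]
        cond += len(sub) / n * entropy_oracle(sub)
    return h_root - cond
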