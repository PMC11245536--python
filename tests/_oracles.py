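"""Independent brute-force oracles shared across test modules."""

import collections
from itertools import combinations


def exact_ranksum_p(a, b):
    """Full permutation-enumeration oracle for the two-sided rank-sum test."""
    pooled = sorted(list(a) + list(b))
    positions = collections.defaultdict(list)
    for i, v in enumerate(pooled, start=1):
        positions[v].append(i)
    rank_of = {v: sum(ps) / len(ps) for v, ps in positions.items()}
    all_ranks = [rank_of[v] for v in pooled]
    n_a = len(a)
    w_obs = sum(rank_of[v] for v in a)
    mean_w = n_a * (len(pooled) + 1) / 2
    count = total = 0
    for comb in combinations(range(len(pooled)), n_a):
        w = sum(all_ranks[i] for i in comb)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total
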