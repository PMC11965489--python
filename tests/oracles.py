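"""Independent brute-force oracles shared across test modules.

These deliberately avoid the library's code paths: plain loops, explicit
enumeration, and textbook formulas only.
"""

import itertools
import math


def exact_wilcoxon_p(a, b):
    """Two-sided rank-sum p by enumerating all group assignments."""
    pooled = sorted(list(a) + list(b))
    ranks = {v: r + 1 for r, v in enumerate(pooled)}
    n_a = len(a)
    u_obs = sum(ranks[v] for v in a) - n_a * (n_a + 1) / 2
    us = [
        sum(ranks[pooled[i]] for i in combo) - n_a * (n_a + 1) / 2
        for combo in itertools.combinations(range(len(pooled)), n_a)
    ]
    n = len(us)
    p = 2 * min(sum(u <= u_obs for u in us) / n, sum(u >= u_obs for u in us) / n)
    return min(p, 1.0)


def average_ranks(keyed, reverse):
    """1-based average ranks of a dict's values (ties share the mean rank)."""
    items = sorted(keyed, key=lambda c: -keyed[c] if reverse else keyed[c])
    ranks = {}
    i = 0
    while i < len(items):
        j = i
        while j < len(items) and keyed[items[j]] == keyed[items[i]]:
            j += 1
        r = (i + 1 + j) / 2
        for c in items[i:j]:
            ranks[c] = r
        i = j
    return ranks


def brute_force_marker_selection(betas, labels, target, n_top):
    """Marker selection oracle: |delta| and Wilcoxon ranks, geometric mean."""
    deltas, ps = {}, {}
    for c in betas.index:
        a = [betas.loc[c, s] for s in betas.columns if labels[s] == target]
        b = [betas.loc[c, s] for s in betas.columns if labels[s] != target]
        deltas[c] = sum(a) / len(a) - sum(b) / len(b)
        ps[c] = exact_wilcoxon_p(a, b)
    rd = average_ranks({c: abs(d) for c, d in deltas.items()}, reverse=True)
    rp = average_ranks(ps, reverse=False)
    combined = {c: math.sqrt(rd[c] * rp[c]) for c in betas.index}
    order = sorted(betas.index, key=lambda c: (combined[c], -abs(deltas[c]), c))
    return order[:n_top]
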