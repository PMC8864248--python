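"""Literal brute-force reference implementations used as test oracles.

These transliterate the method's definitions with plain loops and sets,
independently of the package's vectorized code paths.
"""

import math


def ref_box_size(fraction, n):
    return max(1, math.floor(fraction * n + 0.5))


def ref_box(values, k, b):
    """The b cells nearest in value to cell k; ties by smaller index."""
    n = len(values)
    order = sorted(range(n), key=lambda c: (abs(values[c] - values[k]), c))
    return set(order[:b])


def ref_r(values_i, values_j, k, b):
    n = len(values_i)
    bi = ref_box(values_i, k, b)
    bj = ref_box(values_j, k, b)
    return len(bi & bj) / n - (len(bi) / n) * (len(bj) / n)


def ref_network(values, k, fraction):
    """Edge dict {(i, j): r} with i < j and r > 0, for cell k."""
    m, n = values.shape
    b = ref_box_size(fraction, n)
    edges = {}
    for i in range(m):
        for j in range(i + 1, m):
            r = ref_r(values[i], values[j], k, b)
            if r > 0:
                edges[(i, j)] = r
    return edges


def ref_local_sge(weights, exprs, mode="product"):
    s = len(weights)
    if s <= 1:
        return 0.0
    if mode == "product":
        masses = [w * e for w, e in zip(weights, exprs)]
    elif mode == "r_only":
        masses = list(weights)
    else:
        masses = list(exprs)
    total = sum(masses)
    if total <= 0:
        return 0.0
    h = 0.0
    for mass in masses:
        p = mass / total
        if p > 0:
            h -= p * math.log(p)
    return h / math.log(s)


def ref_local_entropy_matrix(values, fraction, mode="product"):
    """(M, N) local SGE by nested loops over cells, genes and neighbors."""
    m, n = values.shape
    out = [[0.0] * n for _ in range(m)]
    for k in range(n):
        edges = ref_network(values, k, fraction)
        neighbors = {i: [] for i in range(m)}
        for (i, j), r in edges.items():
            neighbors[i].append((j, r))
            neighbors[j].append((i, r))
        for i in range(m):
            ws = [r for _, r in neighbors[i]]
            es = [values[j, k] for j, _ in neighbors[i]]
            out[i][k] = ref_local_sge(ws, es, mode)
    return out


def ref_cell_sge(column, t_fraction):
    t = math.ceil(t_fraction * len(column))
    return sum(sorted(column, reverse=True)[:t]), t
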