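"""Independent brute-force recomputations of the stability statistics.

These deliberately use plain double loops and scalar statistics so they share
no code path with the vectorised implementations they check.
"""

import math
import statistics

import numpy as np


def sd(values):
    return statistics.stdev(values)


def genorm_m_oracle(rq):
    """Per-gene M: explicit double loop over gene pairs."""
    genes, mat = rq.genes, rq.rq
    m = {}
    for j, gj in enumerate(genes):
        vs = []
        for k in range(len(genes)):
            if k == j:
                continue
            ratios = [math.log2(mat[j, i] / mat[k, i]) for i in range(mat.shape[1])]
            vs.append(sd(ratios))
        m[gj] = sum(vs) / len(vs)
    return m


def genorm_exclusion_oracle(rq):
    """Stepwise exclusion by exhaustive recomputation on a shrinking gene list."""
    import refstab

    genes = list(rq.genes)
    mat = {g: rq.rq[i] for i, g in enumerate(genes)}
    order = []
    current = list(genes)
    while len(current) > 2:
        sub = refstab.RQMatrix(current, list(rq.samples), np.array([mat[g] for g in current]))
        m = genorm_m_oracle(sub)
        worst = max(current, key=lambda g: (m[g], g))
        order.append(worst)
        current.remove(worst)
    return order, tuple(sorted(current))


def v_curve_oracle(rq, ranking):
    """V(n, n+1) by direct geometric means and scalar SD."""
    mat = {g: rq.rq[rq.genes.index(g)] for g in ranking}
    n_samples = rq.rq.shape[1]

    def nf(subset):
        return [
            math.prod(mat[g][i] for g in subset) ** (1.0 / len(subset))
            for i in range(n_samples)
        ]

    out = {}
    for n in range(2, len(ranking)):
        a, b = nf(ranking[:n]), nf(ranking[: n + 1])
        out[n] = sd([math.log2(x / y) for x, y in zip(a, b)])
    return out


def delta_ct_oracle(m):
    """Mean pairwise-difference SD by double loop on raw Cq."""
    genes, cq = m.genes, m.cq_mean
    out = {}
    for j, gj in enumerate(genes):
        sds = []
        for k in range(len(genes)):
            if k == j:
                continue
            diffs = [cq[j, i] - cq[k, i] for i in range(cq.shape[1])]
            sds.append(sd(diffs))
        out[gj] = sum(sds) / len(sds)
    return out


def bestkeeper_oracle(m):
    """SD, CV, index and Pearson r from scalar formulas."""
    genes, cq = m.genes, m.cq_mean
    n = cq.shape[1]
    index = [
        math.prod(cq[j, i] for j in range(len(genes))) ** (1.0 / len(genes))
        for i in range(n)
    ]
    out = {}
    for j, g in enumerate(genes):
        row = list(cq[j])
        s = sd(row)
        mean = sum(row) / n
        mi = sum(index) / n
        num = sum((x - mean) * (y - mi) for x, y in zip(row, index))
        den = math.sqrt(sum((x - mean) ** 2 for x in row) * sum((y - mi) ** 2 for y in index))
        out[g] = {"sd": s, "cv": 100.0 * s / mean, "r": num / den if den > 0 else float("nan")}
    return out, index
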