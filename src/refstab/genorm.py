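"""geNorm: pairwise-variation stability measure M, stepwise gene exclusion,
normalization factors and the V(n/n+1) curve for the optimal reference count.

For genes j, k with relative quantities rq, A_jk = log2(rq_j / rq_k) per
sample and V_jk = SD(A_jk) (n-1 denominator).  A gene's stability
M_j = mean over k != j of V_jk; lower M means more stable.  Genes are
eliminated one at a time (highest M first, M recomputed each pass) until a
tied final pair remains.  The pairwise variation V(n, n+1) between
normalization factors built from the n and n+1 most stable genes decides how
many references are needed: the smallest n with V < 0.15 (default cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import RQMatrix

DEFAULT_V_CUTOFF = 0.15


@dataclass
class GenormResult:
    m_values: dict[str, float]  # first-pass M per gene
    exclusion_order: list[tuple[str, float]]  # least->most stable, with M at elimination
    final_pair: tuple[str, str]
    ranking: list[str]  # most stable first (final pair first, alphabetical)
    v_curve: dict[int, float] = field(default_factory=dict)  # n -> V(n, n+1)
    optimal_n: int | None = None  # None when the cutoff is never reached
    cutoff: float = DEFAULT_V_CUTOFF

    def ranks(self, tied_final_pair: bool = True) -> dict[str, float]:
        """Stability ranks (1 = most stable).

        The final pair cannot be separated by the algorithm, so by default
        both its genes get midrank 1.5; ``tied_final_pair=False`` assigns 1
        and 2 in the stored (alphabetical) order.
        """
        ranks: dict[str, float] = {}
        for i, g in enumerate(self.ranking):
            ranks[g] = float(i + 1)
        if tied_final_pair:
            ranks[self.final_pair[0]] = 1.5
            ranks[self.final_pair[1]] = 1.5
        return ranks

    def to_frame(self) -> pd.DataFrame:
        step = {g: i + 1 for i, (g, _) in enumerate(self.exclusion_order)}
        rk = self.ranks()
        rows = [
            {"gene": g, "m_first_pass": self.m_values[g], "exclusion_step": step.get(g), "rank": rk[g]}
            for g in sorted(self.m_values)
        ]
        return pd.DataFrame(rows).set_index("gene")


def pairwise_log_ratio_sd(rq_j: np.ndarray, rq_k: np.ndarray) -> float:
    """V_jk: SD (n-1) across samples of the pairwise log2 expression ratio."""
    rq_j = np.asarray(rq_j, float)
    rq_k = np.asarray(rq_k, float)
    if rq_j.shape != rq_k.shape:
        raise ValueError("rq vectors must have equal length")
    if rq_j.size < 2:
        raise ValueError("need >=2 samples for a pairwise variation")
    if np.any(rq_j <= 0) or np.any(rq_k <= 0):
        raise ValueError("relative quantities must be positive")
    return float(np.std(np.log2(rq_j / rq_k), ddof=1))


def _m_from_log2(y: np.ndarray) -> np.ndarray:
    """Vectorised M for a log2-quantity matrix y (genes x samples)."""
    G = y.shape[0]
    # V[j,k] = SD over samples of y_j - y_k
    diffs = y[:, None, :] - y[None, :, :]
    v = np.std(diffs, axis=2, ddof=1)
    return (v.sum(axis=1)) / (G - 1)  # diagonal contributes 0


def genorm_m(rq: RQMatrix) -> dict[str, float]:
    """First-pass geNorm M per gene: mean pairwise log-ratio SD against all others."""
    if len(rq.genes) < 3:
        raise ValueError("geNorm M requires >=3 genes")
    if len(rq.samples) < 2:
        raise ValueError("geNorm M requires >=2 samples")
    if np.any(rq.rq <= 0):
        raise ValueError("relative quantities must be positive")
    m = _m_from_log2(np.log2(rq.rq))
    return {g: float(v) for g, v in zip(rq.genes, m)}


def genorm_rank(rq: RQMatrix) -> GenormResult:
    """Stepwise exclusion: repeatedly drop the gene with the highest M.

    Ties on the highest M remove the lexicographically later gene id, making
    the procedure deterministic.  The last two genes are reported as a tied
    pair (their M values are equal by construction).
    """
    m_first = genorm_m(rq)
    genes = list(rq.genes)
    y = np.log2(rq.rq)
    order: list[tuple[str, float]] = []
    idx = list(range(len(genes)))
    while len(idx) > 2:
        m = _m_from_log2(y[idx])
        worst = max(range(len(idx)), key=lambda i: (m[i], genes[idx[i]]))
        order.append((genes[idx[worst]], float(m[worst])))
        idx.pop(worst)
    final_m = _m_from_log2(y[idx])
    pair = sorted(genes[i] for i in idx)
    ranking = pair + [g for g, _ in reversed(order)]
    result = GenormResult(
        m_values=m_first,
        exclusion_order=order + [(pair[1], float(final_m[0])), (pair[0], float(final_m[0]))],
        final_pair=(pair[0], pair[1]),
        ranking=ranking,
    )
    return result


def normalization_factor(rq: RQMatrix, subset: list[str]) -> np.ndarray:
    """Per-sample normalization factor: geometric mean of the subset genes' rq."""
    if not subset:
        raise ValueError("reference subset must be nonempty")
    gi = [rq.genes.index(g) for g in subset]
    return np.exp2(np.log2(rq.rq[gi]).mean(axis=0))


def pairwise_variation_curve(
    rq: RQMatrix,
    ranking: list[str],
    cutoff: float = DEFAULT_V_CUTOFF,
) -> tuple[dict[int, float], int | None]:
    """V(n, n+1) = SD over samples of log2(NF_n / NF_{n+1}) for n = 2..G-1.

    ``ranking`` lists genes from most to least stable; ``optimal_n`` is the
    smallest n whose V falls below the cutoff, or None if never reached.
    """
    G = len(ranking)
    if G < 3:
        raise ValueError("V-curve requires >=3 ranked genes")
    v_curve: dict[int, float] = {}
    nf_log = None
    for n in range(2, G):
        if nf_log is None:
            nf_log = np.log2(normalization_factor(rq, ranking[:n]))
        nf_next_log = np.log2(normalization_factor(rq, ranking[: n + 1]))
        v_curve[n] = float(np.std(nf_log - nf_next_log, ddof=1))
        nf_log = nf_next_log
    optimal_n = next((n for n in sorted(v_curve) if v_curve[n] < cutoff), None)
    return v_curve, optimal_n


def genorm_full(rq: RQMatrix, cutoff: float = DEFAULT_V_CUTOFF) -> GenormResult:
    """Stepwise ranking plus the V-curve in one call."""
    res = genorm_rank(rq)
    res.cutoff = cutoff
    res.v_curve, res.optimal_n = pairwise_variation_curve(rq, res.ranking, cutoff)
    return res
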