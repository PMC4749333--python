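"""Efficiency-corrected relative expression with a randomization test.

The validation stage of a reference-gene study: the fold change of a target
gene between a control and a treated condition, normalized by one or more
reference genes,

    R = (1+E_t)^(meanCq_t,ctrl - meanCq_t,trt)
        / geomean over refs r of (1+E_r)^(meanCq_r,ctrl - meanCq_r,trt),

with significance from a fixed-reallocation randomization test: condition
labels are reassigned jointly across target and reference genes (whole-sample
reallocation, preserving within-sample pairing), R is recomputed for each
reallocation, and the two-sided p-value is the smoothed proportion of
permuted |log R| at least as large as observed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class ExpressionRatioResult:
    target: str
    ratio: float  # fold change, > 0
    reference_set: tuple[str, ...]
    per_replicate_ratios: np.ndarray  # one ratio per treated replicate
    p_value: float | None = None
    n_permutations: int | None = None


def _as_frame(table) -> pd.DataFrame:
    frame = pd.DataFrame(table)
    if frame.isna().any().any():
        raise ValueError("missing Cq values in replicate table")
    return frame.astype(float)


def _log_weights(genes: list[str], eff: dict[str, float]) -> np.ndarray:
    w = np.empty(len(genes))
    for i, g in enumerate(genes):
        if g not in eff:
            raise ValueError(f"no efficiency for gene {g}")
        if eff[g] <= 0:
            raise ValueError(f"gene {g}: efficiency must be positive")
        w[i] = math.log2(1.0 + eff[g])
    return w


def expression_ratio(
    cq_control: pd.DataFrame,
    cq_treated: pd.DataFrame,
    target: str,
    references: list[str],
    eff: dict[str, float],
) -> ExpressionRatioResult:
    """Fold change of ``target`` between conditions, normalized by ``references``.

    ``cq_control`` / ``cq_treated`` are genes-x-replicates tables containing
    the target and all reference genes.  Multi-reference normalization uses
    the geometric mean of the per-reference correction factors.
    """
    if not references:
        raise ValueError("reference set must be nonempty")
    genes = [target] + list(references)
    ctrl = _as_frame(cq_control).loc[genes]
    trt = _as_frame(cq_treated).loc[genes]
    if ctrl.shape[1] < 2 or trt.shape[1] < 2:
        raise ValueError("need >=2 replicates per condition")
    w = _log_weights(genes, eff)

    d_cq = ctrl.to_numpy().mean(axis=1) - trt.to_numpy().mean(axis=1)
    log_r = w[0] * d_cq[0] - np.mean(w[1:] * d_cq[1:])

    # per treated replicate, against the control means
    d_rep = ctrl.to_numpy().mean(axis=1)[:, None] - trt.to_numpy()
    log_rep = w[0] * d_rep[0] - np.mean(w[1:, None] * d_rep[1:], axis=0)

    return ExpressionRatioResult(
        target=target,
        ratio=float(2.0**log_r),
        reference_set=tuple(references),
        per_replicate_ratios=np.exp2(log_rep),
    )


def randomization_test(
    cq_control: pd.DataFrame,
    cq_treated: pd.DataFrame,
    target: str,
    references: list[str],
    eff: dict[str, float],
    n_permutations: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionRatioResult:
    """Fixed-reallocation randomization test on the expression ratio.

    Replicate samples keep their gene-wise Cq profile intact; only their
    condition label is reallocated.  Two-sided p-value on |log R| with +1
    smoothing: p = (1 + #{|log R*| >= |log R|}) / (1 + n_permutations).
    With fewer than 10 distinct reallocations the full set is enumerated
    instead (with a warning) and p is the exact proportion.
    """
    result = expression_ratio(cq_control, cq_treated, target, references, eff)
    genes = [target] + list(references)
    ctrl = _as_frame(cq_control).loc[genes].to_numpy()
    trt = _as_frame(cq_treated).loc[genes].to_numpy()
    n_c, n_t = ctrl.shape[1], trt.shape[1]
    w = _log_weights(genes, eff)

    # log R is linear in the per-gene condition-mean difference, so collapse
    # each replicate to a single contrast value z before permuting labels
    v = np.concatenate([[w[0]], -w[1:] / len(references)])
    z = v @ np.hstack([ctrl, trt])  # length n_c + n_t
    obs = abs(z[:n_c].mean() - z[n_c:].mean())

    n_total = n_c + n_t
    n_distinct = math.comb(n_total, n_c)
    if n_distinct < 10:
        warnings.warn(
            f"only {n_distinct} distinct reallocations; using exact enumeration",
            stacklevel=2,
        )
        stats_all = [
            abs(z[list(c)].mean() - z[[i for i in range(n_total) if i not in c]].mean())
            for c in combinations(range(n_total), n_c)
        ]
        p = float(np.mean(np.asarray(stats_all) >= obs - 1e-12))
        result.p_value = p
        result.n_permutations = n_distinct
        return result

    if rng is None:
        rng = np.random.default_rng(seed)
    labels = np.zeros((n_permutations, n_total), dtype=bool)
    labels[:, :n_c] = True
    labels = rng.permuted(labels, axis=1)
    mean_c = (labels @ z) / n_c
    mean_t = ((~labels) @ z) / n_t
    perm = np.abs(mean_c - mean_t)
    result.p_value = float((1 + np.sum(perm >= obs - 1e-12)) / (1 + n_permutations))
    result.n_permutations = n_permutations
    return result
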