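"""Model-based stability estimation (NormFinder-style).

Works on y = log2(relative quantity).  The model decomposes a gene's
expression into a sample effect (common load), a gene effect, an optional
systematic group x gene interaction d_gj (intergroup deviation), and residual
intragroup noise with per-gene variance sigma^2_gj.  A candidate reference
gene is penalised both for drifting between groups (|d_gj|) and for
fluctuating within them (sqrt(sigma^2_gj / n_g)); the stability value is the
group-averaged sum of the two.  In the ungrouped mode the stability value is
simply the SD of the gene's two-way-centered residuals.  Lower = more stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import RQMatrix


@dataclass
class NormfinderResult:
    stability: dict[str, float]  # rho per gene, log2 scale, >= 0
    grouped: bool
    intragroup_var: pd.DataFrame | None = None  # genes x groups, sigma^2_gj
    intergroup_dev: pd.DataFrame | None = None  # genes x groups, d_gj

    def ranking(self) -> list[str]:
        return sorted(self.stability, key=lambda g: (self.stability[g], g))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"stability": pd.Series(self.stability)})
        frame["rank"] = frame["stability"].rank(method="average")
        return frame.sort_index()


def _two_way_center(y: np.ndarray) -> np.ndarray:
    """Remove per-sample (column) and per-gene (row) means, add grand mean."""
    return y - y.mean(axis=0, keepdims=True) - y.mean(axis=1, keepdims=True) + y.mean()


def _residual_var(y: np.ndarray, correct: bool) -> np.ndarray:
    """Per-gene variance of two-way-centered residuals.

    The naive residual variance s2_j is biased: centering across J genes leaks
    every gene's noise into every residual, E[s2_j] = sigma2_j(1-2/J) +
    sum(sigma2)/J^2.  Solving the moment equations gives the corrected
    estimator sigma2_j = (J/(J-2)) * (s2_j - sum(s2)/(J(J-1))), clamped at 0.
    """
    J, n = y.shape
    if n < 2:
        raise ValueError("need >=2 samples per group for a variance estimate")
    r = _two_way_center(y)
    s2 = np.sum(r**2, axis=1) / (n - 1)
    if not correct or J <= 2:
        return s2
    sigma2 = (J / (J - 2)) * (s2 - s2.sum() / (J * (J - 1)))
    return np.clip(sigma2, 0.0, None)


def normfinder_stability(
    rq: RQMatrix,
    groups: dict[str, str] | None = None,
    small_sample_correction: bool = True,
) -> NormfinderResult:
    """Stability value per gene, grouped (requires >=2 samples per group) or not.

    Parameters
    ----------
    rq
        Relative quantities (genes x samples), all positive.
    groups
        Optional map sample_id -> group label.  With groups, stability is
        rho_j = mean over groups g of (|d_gj| + sqrt(sigma^2_gj / n_g)).
        Without, rho_j = sqrt(sigma^2_j) from whole-set two-way centering.
    small_sample_correction
        Apply the J/(J-2) bias correction to the intragroup variance
        estimates (J = number of genes).
    """
    genes = list(rq.genes)
    if len(genes) < 3:
        raise ValueError("NormFinder requires >=3 genes")
    y = np.log2(rq.rq)

    if groups is None:
        sigma2 = _residual_var(y, small_sample_correction)
        rho = np.sqrt(sigma2)
        return NormfinderResult(
            stability={g: float(r) for g, r in zip(genes, rho)}, grouped=False
        )

    labels = [groups[s] for s in rq.samples]
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("grouped mode requires >=2 groups")
    cols = {u: [i for i, l in enumerate(labels) if l == u] for u in uniq}
    for u, idx in cols.items():
        if len(idx) < 2:
            raise ValueError(f"group {u!r} has {len(idx)} sample(s); grouped mode requires >=2 per group")

    J = len(genes)
    n_groups = len(uniq)
    sigma2 = np.empty((J, n_groups))
    group_gene_mean = np.empty((J, n_groups))
    for c, u in enumerate(uniq):
        sub = y[:, cols[u]]
        sigma2[:, c] = _residual_var(sub, small_sample_correction)
        # remove the group's sample effects before taking the gene mean
        group_gene_mean[:, c] = (sub - sub.mean(axis=0, keepdims=True)).mean(axis=1)

    # intergroup deviation: double-center the gene x group mean table so d_gj
    # sums to zero over genes within a group and over groups within a gene
    d = _two_way_center(group_gene_mean)

    n_g = np.array([len(cols[u]) for u in uniq], dtype=float)
    rho = (np.abs(d) + np.sqrt(sigma2 / n_g[None, :])).mean(axis=1)
    return NormfinderResult(
        stability={g: float(r) for g, r in zip(genes, rho)},
        grouped=True,
        intragroup_var=pd.DataFrame(sigma2, index=genes, columns=uniq),
        intergroup_dev=pd.DataFrame(d, index=genes, columns=uniq),
    )
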