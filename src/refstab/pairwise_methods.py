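"""BestKeeper descriptive stability and the comparative delta-Ct method.

Both consume raw mean Cq (no efficiency correction), as the original tools
do.  BestKeeper ranks genes by the sample SD of their Cq and reports the
Pearson correlation of each gene with the BestKeeper index (per-sample
geometric mean of Cq over all candidates).  The comparative delta-Ct method
scores a gene by the mean, over all partner genes, of the SD of the pairwise
Cq difference across samples; a stable pair keeps a constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qpcr_data import CqMatrix


@dataclass
class BestKeeperResult:
    sd_cq: dict[str, float]  # cycles
    cv_cq: dict[str, float]  # % of mean Cq
    index: np.ndarray  # per-sample geometric mean of Cq
    pearson_r: dict[str, float]  # NaN when the index has zero variance
    rank_key: str = "sd"

    def ranking(self) -> list[str]:
        if self.rank_key == "sd":
            return sorted(self.sd_cq, key=lambda g: (self.sd_cq[g], g))
        # r-based: stronger correlation with the index = more stable
        return sorted(self.pearson_r, key=lambda g: (-abs(self.pearson_r[g]), g))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"sd_cq": pd.Series(self.sd_cq), "cv_cq": pd.Series(self.cv_cq), "pearson_r": pd.Series(self.pearson_r)}
        )
        key = frame["sd_cq"] if self.rank_key == "sd" else -frame["pearson_r"].abs()
        frame["rank"] = key.rank(method="average")
        return frame.sort_index()


@dataclass
class DeltaCtResult:
    mean_pairwise_sd: dict[str, float]  # cycles

    def ranking(self) -> list[str]:
        return sorted(self.mean_pairwise_sd, key=lambda g: (self.mean_pairwise_sd[g], g))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"score": pd.Series(self.mean_pairwise_sd)})
        frame["rank"] = frame["score"].rank(method="average")
        return frame.sort_index()


def _complete_cq(m: CqMatrix, min_genes: int, min_samples: int) -> np.ndarray:
    if len(m.genes) < min_genes:
        raise ValueError(f"need >={min_genes} genes")
    complete = np.isfinite(m.cq_mean).all(axis=0)
    cq = m.cq_mean[:, complete]
    if cq.shape[1] < min_samples:
        raise ValueError(f"need >={min_samples} complete samples, have {cq.shape[1]}")
    return cq


def bestkeeper(m: CqMatrix, rank_key: str = "sd") -> BestKeeperResult:
    """BestKeeper statistics on raw Cq; samples with any missing gene dropped."""
    if rank_key not in {"sd", "r"}:
        raise ValueError("rank_key must be 'sd' or 'r'")
    cq = _complete_cq(m, min_genes=2, min_samples=3)
    sd = np.std(cq, axis=1, ddof=1)
    mean = cq.mean(axis=1)
    index = stats.gmean(cq, axis=0)
    r = np.full(len(m.genes), np.nan)
    if np.std(index) > 0:
        for j in range(len(m.genes)):
            if np.std(cq[j]) > 0:
                r[j] = stats.pearsonr(cq[j], index)[0]
    return BestKeeperResult(
        sd_cq={g: float(s) for g, s in zip(m.genes, sd)},
        cv_cq={g: float(100.0 * s / mu) for g, s, mu in zip(m.genes, sd, mean)},
        index=index,
        pearson_r={g: float(v) for g, v in zip(m.genes, r)},
        rank_key=rank_key,
    )


def delta_ct_stability(m: CqMatrix) -> DeltaCtResult:
    """Comparative delta-Ct score: mean over partners of SD of pairwise Cq differences."""
    cq = _complete_cq(m, min_genes=3, min_samples=2)
    diffs = cq[:, None, :] - cq[None, :, :]
    sd = np.std(diffs, axis=2, ddof=1)
    score = sd.sum(axis=1) / (len(m.genes) - 1)
    return DeltaCtResult({g: float(s) for g, s in zip(m.genes, score)})
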