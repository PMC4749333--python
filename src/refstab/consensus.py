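"""Comprehensive ranking: per-method stability ranks aggregated by geometric mean.

Each of the four stability algorithms (geNorm, NormFinder, BestKeeper,
comparative delta-Ct) produces a rank per gene (1 = most stable, midranks for
ties; geNorm's inseparable final pair contributes 1.5/1.5 by default).  The
consensus score is the geometric mean of a gene's four ranks, and the
comprehensive order sorts it ascending with a lexicographic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

METHODS = ("genorm", "normfinder", "bestkeeper", "deltact")


@dataclass
class StabilityTable:
    """Per-gene method ranks, geometric-mean rank and comprehensive order."""

    method_ranks: pd.DataFrame  # genes x methods
    geomean_rank: pd.Series
    comprehensive_rank: pd.Series  # integer 1..G

    def ranking(self) -> list[str]:
        return list(self.comprehensive_rank.sort_values().index)

    def to_frame(self) -> pd.DataFrame:
        out = self.method_ranks.copy()
        out["geomean_rank"] = self.geomean_rank
        out["comprehensive_rank"] = self.comprehensive_rank
        return out.sort_values("comprehensive_rank")


def rank_scores(scores: dict[str, float], ascending: bool = True) -> dict[str, float]:
    """Rank genes by score (rank 1 = most stable = lowest when ascending); ties midrank."""
    ser = pd.Series(scores, dtype=float)
    if not np.isfinite(ser).all():
        bad = ser.index[~np.isfinite(ser)][0]
        raise ValueError(f"non-finite score for gene {bad!r}")
    ranks = ser.rank(method="average", ascending=ascending)
    return {g: float(r) for g, r in ranks.items()}


def comprehensive_rank(method_ranks: pd.DataFrame) -> StabilityTable:
    """Aggregate per-method ranks by geometric mean.

    ``method_ranks``: genes as index, one column per method.  Every gene must
    be ranked by every method.
    """
    if method_ranks.shape[1] < 2:
        raise ValueError("need >=2 methods to aggregate")
    if method_ranks.isna().any().any():
        gene = method_ranks.index[method_ranks.isna().any(axis=1)][0]
        raise ValueError(f"gene {gene!r} missing a rank in at least one method")
    geo = pd.Series(stats.gmean(method_ranks.to_numpy(), axis=1), index=method_ranks.index)
    order = sorted(geo.index, key=lambda g: (geo[g], g))
    comp = pd.Series({g: i + 1 for i, g in enumerate(order)}, dtype=int)
    return StabilityTable(method_ranks.copy(), geo, comp.reindex(method_ranks.index))
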