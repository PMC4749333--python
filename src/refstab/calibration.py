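"""Standard-curve fitting, amplification efficiency, and relative quantities.

A dilution series of template amounts d (e.g. 1, 1/2, ..., 1/16) gives a
straight line Cq = intercept + slope * log10(d); the amplification efficiency
follows from the slope as E = 10^(-1/slope) - 1, so slope = -3.3219 means
perfect doubling (E = 1).  Raw Cq values are then converted to linear-scale
relative quantities RQ = (1+E)^(minCq - Cq), calibrated so the most abundant
sample of each gene gets RQ = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qpcr_data import CqMatrix

#: efficiencies above this are biologically implausible and rejected
MAX_EFFICIENCY = 1.2
#: efficiencies above this trigger a warning (over-unity amplification)
WARN_EFFICIENCY = 1.1


@dataclass
class DilutionSeries:
    """Mean Cq per point of a serial dilution of one gene's template."""

    gene: str
    dilution_factors: np.ndarray  # relative template amounts, strictly decreasing
    cq: np.ndarray  # cycles

    def __post_init__(self) -> None:
        self.dilution_factors = np.asarray(self.dilution_factors, dtype=float)
        self.cq = np.asarray(self.cq, dtype=float)
        if self.dilution_factors.size < 3:
            raise ValueError(f"gene {self.gene}: need >=3 dilution points, got {self.dilution_factors.size}")
        if np.any(self.dilution_factors <= 0):
            raise ValueError(f"gene {self.gene}: dilution factors must be positive")
        if np.any(np.diff(self.dilution_factors) >= 0):
            raise ValueError(f"gene {self.gene}: dilution factors must be strictly decreasing")
        if self.cq.shape != self.dilution_factors.shape:
            raise ValueError(f"gene {self.gene}: cq and dilution_factors length mismatch")


@dataclass
class StandardCurve:
    """OLS fit of Cq against log10(template amount)."""

    gene: str
    slope: float  # cycles per log10 template; negative for a valid curve
    intercept: float  # cycles at d = 1
    r_squared: float
    efficiency: float | None  # E = 10^(-1/slope) - 1; None when slope >= 0
    valid: bool


@dataclass
class RQMatrix:
    """Efficiency-corrected relative quantities per gene x sample (linear scale)."""

    genes: list[str]
    samples: list[str]
    rq: np.ndarray  # (n_genes, n_samples), all > 0
    calibrator_policy: str = "per-gene minimum Cq within the analyzed sample set"

    def __post_init__(self) -> None:
        self.rq = np.asarray(self.rq, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rq, index=self.genes, columns=self.samples)

    def log2(self) -> np.ndarray:
        return np.log2(self.rq)


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E = 10^(-1/slope) - 1 from a standard-curve slope."""
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return float(10.0 ** (-1.0 / slope) - 1.0)


def fit_standard_curve(s: DilutionSeries) -> StandardCurve:
    """Ordinary least-squares fit of Cq on log10(dilution factor).

    A non-negative slope (no dilution response) yields ``valid=False`` with
    ``efficiency=None`` rather than an exception, so batch calibration can
    report per-gene failures.
    """
    x = np.log10(s.dilution_factors)
    y = s.cq
    if np.allclose(y, y[0]):
        return StandardCurve(s.gene, 0.0, float(y[0]), 0.0, None, valid=False)
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue**2)
    if slope >= 0:
        return StandardCurve(s.gene, slope, intercept, r2, None, valid=False)
    eff = efficiency_from_slope(slope)
    return StandardCurve(s.gene, slope, intercept, r2, eff, valid=True)


def read_dilution_csv(path) -> list[DilutionSeries]:
    """Read a long CSV with columns gene, dilution_factor, cq."""
    table = pd.read_csv(path)
    out = []
    for gene, grp in table.groupby("gene", sort=False):
        grp = grp.sort_values("dilution_factor", ascending=False)
        out.append(DilutionSeries(str(gene), grp["dilution_factor"].to_numpy(), grp["cq"].to_numpy()))
    return out


def read_efficiency_csv(path) -> dict[str, float]:
    """Read per-gene efficiencies (fractions, e.g. 0.90-1.09) from a two-column CSV."""
    table = pd.read_csv(path)
    return {str(g): float(e) for g, e in zip(table["gene"], table["efficiency"])}


def _check_efficiencies(genes: list[str], eff: dict[str, float]) -> np.ndarray:
    vals = np.empty(len(genes))
    for i, g in enumerate(genes):
        if g not in eff:
            raise ValueError(f"no efficiency for gene {g}")
        e = eff[g]
        if e <= 0:
            raise ValueError(f"gene {g}: efficiency must be positive, got {e}")
        if e > MAX_EFFICIENCY:
            raise ValueError(f"gene {g}: efficiency {e} exceeds plausible maximum {MAX_EFFICIENCY}")
        if e > WARN_EFFICIENCY:
            warnings.warn(f"gene {g}: over-unity efficiency {e} (> {WARN_EFFICIENCY})", stacklevel=3)
        vals[i] = e
    return vals


def to_relative_quantities(m: CqMatrix, eff: dict[str, float]) -> RQMatrix:
    """Convert mean Cq to relative quantities rq = (1+E)^(minCq - Cq).

    The calibrator is the per-gene minimum Cq within the supplied matrix (the
    analyzed sample set), so each gene's largest rq is exactly 1.  Samples
    missing any gene's Cq are dropped (listwise within the set) so every
    downstream pairwise statistic sees complete columns.
    """
    e = _check_efficiencies(m.genes, eff)
    all_missing = ~np.isfinite(m.cq_mean).any(axis=1)
    if all_missing.any():
        raise ValueError(f"gene {m.genes[int(np.argmax(all_missing))]}: all Cq missing")
    complete = np.isfinite(m.cq_mean).all(axis=0)
    if not complete.any():
        raise ValueError("no sample has complete Cq across all genes")
    cq = m.cq_mean[:, complete]
    samples = [s for s, keep in zip(m.samples, complete) if keep]
    min_cq = cq.min(axis=1, keepdims=True)
    rq = (1.0 + e)[:, None] ** (min_cq - cq)
    return RQMatrix(list(m.genes), samples, rq)
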