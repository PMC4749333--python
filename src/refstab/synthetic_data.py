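"""Synthetic Cq data with known ground truth.

Emulates the design of a 25-candidate reference-gene screen in chickpea:
20 biological samples organised into four overlapping sets (9 genotypes,
8 abiotic-stress leaf samples, 5 tissues, and all 20 together, with the
cultivar JG11 as the shared control), 3 biological x 3 technical replicates,
gene-specific amplification efficiencies in the 0.90-1.09 range, and
per-gene expression noise on the log2 scale that defines the true stability
order.  The model per biological observation i and gene j is

    x_ij = beta_{group(i), j} + s_i + eps_ij      (log2 expression)
    Cq_ij = a_j - x_ij / log2(1 + E_j)            (cycles)

with s_i ~ N(0, sample_effect_sd^2) a common loading effect,
eps_ij ~ N(0, tau_j^2) the gene's stability noise, a_j the baseline Cq and
E_j the gene's efficiency; technical replicates add N(0, tech_rep_sd^2)
cycles.  Noise is injected on the log2 scale because every stability
statistic measures log-scale dispersion, so tau_j is the ground truth the
methods are asked to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import DilutionSeries
from .qpcr_data import CqDataset, SampleRecord

LOG2_10 = np.log2(10.0)

#: default biological samples: (sample_id, sets, group label, is_control);
#: JG11 is the shared control across all four sets
DEFAULT_DESIGN: tuple[tuple[str, tuple[str, ...], str, bool], ...] = (
    ("JG11", ("genotypes", "stress", "tissues", "all"), "control", True),
    # eight further genotypes (cultivated and wild)
    *(
        (f"GEN{i:02d}", ("genotypes", "all"), f"GEN{i:02d}", False)
        for i in range(2, 10)
    ),
    # seven abiotic-stress leaf treatments (JG11 is the stress control)
    *(
        (f"STR_{t}", ("stress", "all"), t, False)
        for t in ("drought", "salt", "vpd", "aba", "cold", "heat", "drought_ctrl")
    ),
    # four tissues besides the control leaf
    *(
        (f"TIS_{t}", ("tissues", "all"), t, False)
        for t in ("flower", "root", "seedling", "seed")
    ),
)


@dataclass
class SimulationConfig:
    """Generator settings; defaults mirror the emulated study design."""

    n_genes: int = 25
    design: tuple = DEFAULT_DESIGN
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    baseline_cq_range: tuple[float, float] = (19.0, 28.0)
    efficiency_range: tuple[float, float] = (0.90, 1.09)
    tau: np.ndarray | None = None  # per-gene stability noise SD (log2); default ascending 0.02-0.8
    group_effects: dict[str, np.ndarray] | None = None  # group label -> per-gene log2 shift
    sample_effect_sd: float = 0.3  # log2; template-loading variation
    tech_rep_sd: float = 0.15  # cycles
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("n_genes must be >= 3")
        if self.seed is None:
            raise ValueError("seed is required for reproducibility")
        if self.tau is None:
            self.tau = np.linspace(0.02, 0.8, self.n_genes)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.shape != (self.n_genes,):
            raise ValueError("tau must have one SD per gene")
        if np.any(self.tau < 0) or self.sample_effect_sd < 0 or self.tech_rep_sd < 0:
            raise ValueError("all noise SDs must be >= 0")
        if self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ValueError("replicate counts must be >= 1")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    true_log2_expression: pd.DataFrame  # genes x observations
    tau: dict[str, float]
    efficiencies: dict[str, float]
    baseline_cq: dict[str, float]
    stability_order: list[str]  # most stable (lowest tau) first

    def to_json(self, path) -> None:
        payload = {
            "tau": self.tau,
            "efficiencies": self.efficiencies,
            "baseline_cq": self.baseline_cq,
            "stability_order": self.stability_order,
            "true_log2_expression": {
                "genes": list(self.true_log2_expression.index),
                "observations": list(self.true_log2_expression.columns),
                "values": self.true_log2_expression.to_numpy().tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def simulate_cq_dataset(cfg: SimulationConfig) -> tuple[CqDataset, GroundTruth]:
    """Draw a full Cq dataset plus its ground truth, deterministically per seed."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"gene{j + 1:02d}" for j in range(cfg.n_genes)]
    baseline = rng.uniform(*cfg.baseline_cq_range, size=cfg.n_genes)
    eff = rng.uniform(*cfg.efficiency_range, size=cfg.n_genes)

    observations: list[str] = []
    sheet: dict[str, SampleRecord] = {}
    groups: list[str] = []
    for sample_id, sets, group, is_control in cfg.design:
        for b in range(1, cfg.n_bio_reps + 1):
            obs = f"{sample_id}__b{b}"
            observations.append(obs)
            groups.append(group)
            sheet[obs] = SampleRecord(
                sample_id=sample_id,
                biological_replicate_id=f"b{b}",
                set_memberships=frozenset(sets),
                group_label=group,
                is_control=is_control,
            )

    n_obs = len(observations)
    beta = np.zeros((cfg.n_genes, n_obs))
    if cfg.group_effects:
        for i, g in enumerate(groups):
            if g in cfg.group_effects:
                shift = np.asarray(cfg.group_effects[g], dtype=float)
                if shift.shape != (cfg.n_genes,):
                    raise ValueError(f"group effect for {g!r} must have one value per gene")
                beta[:, i] = shift

    s = rng.normal(0.0, cfg.sample_effect_sd, size=n_obs)
    eps = rng.normal(0.0, 1.0, size=(cfg.n_genes, n_obs)) * cfg.tau[:, None]
    x = beta + s[None, :] + eps

    cycles_per_log2 = 1.0 / np.log2(1.0 + eff)  # cycles per log2 expression unit
    cq_bio = baseline[:, None] - x * cycles_per_log2[:, None]
    tech = rng.normal(0.0, cfg.tech_rep_sd, size=(cfg.n_genes, n_obs, cfg.n_tech_reps))
    cq = cq_bio[:, :, None] + tech

    dataset = CqDataset(genes=genes, observations=observations, cq=cq, sample_sheet=sheet)
    order = [genes[j] for j in np.argsort(cfg.tau, kind="stable")]
    truth = GroundTruth(
        true_log2_expression=pd.DataFrame(x, index=genes, columns=observations),
        tau={g: float(t) for g, t in zip(genes, cfg.tau)},
        efficiencies={g: float(e) for g, e in zip(genes, eff)},
        baseline_cq={g: float(a) for g, a in zip(genes, baseline)},
        stability_order=order,
    )
    return dataset, truth


def simulate_dilution_series(
    E_true: float,
    n_points: int = 5,
    step: float = 2.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    gene: str = "gene",
    intercept: float = 20.0,
) -> DilutionSeries:
    """Cq values on the exact standard-curve line plus optional cycle noise.

    The line is Cq(d) = intercept + slope * log10(d) with
    slope = -1 / log10(1 + E_true), i.e. a ``step``-fold dilution series with
    perfect doubling (E=1) rises one cycle per 2-fold dilution.
    """
    if E_true <= 0:
        raise ValueError("E_true must be positive")
    if n_points < 3:
        raise ValueError("need >=3 dilution points")
    d = step ** -np.arange(n_points, dtype=float)  # 1, 1/step, 1/step^2, ...
    slope = -1.0 / np.log10(1.0 + E_true)
    cq = intercept + slope * np.log10(d)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cq = cq + rng.normal(0.0, noise_sd, size=n_points)
    return DilutionSeries(gene=gene, dilution_factors=d, cq=cq)


def simulate_validation_scenario(
    fold_change: float,
    stable_refs: int = 2,
    unstable_refs: int = 2,
    unstable_ref_shift: float = 0.0,
    reps: int = 3,
    noise_sd: float = 0.0,
    seed: int | None = None,
    target: str = "TIP3_1",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Control/treated per-replicate Cq tables for the validation experiment.

    The target gene truly shifts by log2(fold_change); stable reference genes
    stay put; unstable references shift by ``unstable_ref_shift`` log2 units
    under treatment (the bias that normalizing by an unstable gene causes).
    All efficiencies are 1 so fold changes map to cycles one-to-one.
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    rng = np.random.default_rng(seed)
    stable_names = [f"REF_S{i + 1}" for i in range(stable_refs)]
    unstable_names = [f"REF_U{i + 1}" for i in range(unstable_refs)]
    genes = [target] + stable_names + unstable_names
    base = {target: 24.0}
    base.update({g: 20.0 + i for i, g in enumerate(stable_names + unstable_names)})

    shift = {g: 0.0 for g in genes}
    shift[target] = float(np.log2(fold_change))
    for g in unstable_names:
        shift[g] = float(unstable_ref_shift)

    cols_c = [f"c{r + 1}" for r in range(reps)]
    cols_t = [f"t{r + 1}" for r in range(reps)]
    ctrl = pd.DataFrame(
        {c: [base[g] for g in genes] for c in cols_c}, index=genes, dtype=float
    )
    trt = pd.DataFrame(
        {c: [base[g] - shift[g] for g in genes] for c in cols_t}, index=genes, dtype=float
    )
    if noise_sd > 0:
        ctrl += rng.normal(0.0, noise_sd, size=ctrl.shape)
        trt += rng.normal(0.0, noise_sd, size=trt.shape)

    truth = {
        "target": target,
        "fold_change": float(fold_change),
        "stable_refs": stable_names,
        "unstable_refs": unstable_names,
        "unstable_ref_shift_log2": float(unstable_ref_shift),
        "efficiencies": {g: 1.0 for g in genes},
    }
    return ctrl, trt, truth
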