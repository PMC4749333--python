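"""Data model, I/O, replicate aggregation and descriptive statistics for Cq tables.

A qPCR experiment produces quantification-cycle (Cq) values per gene for a
number of biological observations, each measured in several technical
replicates.  :class:`CqDataset` holds the raw three-axis table
(gene x observation x technical replicate) together with a sample sheet that
maps every observation to its biological sample, replicate id, sample-set
memberships and group label.  :func:`aggregate_replicates` collapses it to a
:class:`CqMatrix` (gene x biological sample) by averaging technical replicates
within an observation and then biological replicates within a sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CQ_MIN = 0.0
CQ_MAX = 50.0

#: sample-set names used throughout the pipeline
KNOWN_SETS = ("genotypes", "stress", "tissues", "all")


class CqValidationError(ValueError):
    """Raised when a Cq table or sample sheet violates its invariants."""


@dataclass
class SampleRecord:
    """Metadata for one biological observation (one column group of the table)."""

    sample_id: str
    biological_replicate_id: str
    set_memberships: frozenset[str]
    group_label: str
    is_control: bool = False


@dataclass
class CqDataset:
    """Raw Cq values: gene x observation x technical replicate, plus metadata.

    ``observations`` are biological-replicate-level measurement units; several
    observations share one ``sample_id`` (the biological sample).  Missing Cq
    values are NaN.
    """

    genes: list[str]
    observations: list[str]
    cq: np.ndarray  # shape (n_genes, n_observations, n_tech_reps), NaN = missing
    sample_sheet: dict[str, SampleRecord]

    def __post_init__(self) -> None:
        self.cq = np.asarray(self.cq, dtype=float)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise CqValidationError("duplicate gene identifiers")
        if len(set(self.observations)) != len(self.observations):
            raise CqValidationError("duplicate observation identifiers")
        if self.cq.ndim != 3 or self.cq.shape[:2] != (len(self.genes), len(self.observations)):
            raise CqValidationError(
                f"cq array shape {self.cq.shape} does not match "
                f"{len(self.genes)} genes x {len(self.observations)} observations"
            )
        finite = self.cq[np.isfinite(self.cq)]
        if finite.size and (np.any(finite <= CQ_MIN) | np.any(finite >= CQ_MAX)):
            bad = np.argwhere(np.isfinite(self.cq) & ((self.cq <= CQ_MIN) | (self.cq >= CQ_MAX)))
            g, o, r = bad[0]
            raise CqValidationError(
                f"Cq value {self.cq[g, o, r]:g} outside ({CQ_MIN:g}, {CQ_MAX:g}) "
                f"at gene={self.genes[g]}, observation={self.observations[o]}, replicate={r + 1}"
            )
        missing = [o for o in self.observations if o not in self.sample_sheet]
        if missing:
            raise CqValidationError(f"observations missing from sample sheet: {missing}")
        for obs, rec in self.sample_sheet.items():
            if not rec.set_memberships:
                raise CqValidationError(f"observation {obs} belongs to no sample set")
            unknown = rec.set_memberships - set(KNOWN_SETS)
            if unknown:
                raise CqValidationError(f"observation {obs} in unknown set(s) {sorted(unknown)}")
            # "all" must be a superset of the union of the specific sets
            if rec.set_memberships - {"all"} and "all" not in rec.set_memberships:
                raise CqValidationError(f"observation {obs} belongs to a specific set but not to 'all'")

    # -- convenience -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        """Unique biological sample ids, in first-appearance order."""
        seen: dict[str, None] = {}
        for obs in self.observations:
            seen.setdefault(self.sample_sheet[obs].sample_id, None)
        return list(seen)

    def samples_in_set(self, set_name: str) -> list[str]:
        if set_name not in KNOWN_SETS:
            raise ValueError(f"unknown sample set {set_name!r}; expected one of {KNOWN_SETS}")
        out: dict[str, None] = {}
        for obs in self.observations:
            rec = self.sample_sheet[obs]
            if set_name in rec.set_memberships:
                out.setdefault(rec.sample_id, None)
        return list(out)

    def group_labels(self) -> dict[str, str]:
        """Map sample_id -> group label."""
        out: dict[str, str] = {}
        for obs in self.observations:
            rec = self.sample_sheet[obs]
            out.setdefault(rec.sample_id, rec.group_label)
        return out


@dataclass
class CqMatrix:
    """Aggregated Cq values per gene x biological sample, with replicate spread."""

    genes: list[str]
    samples: list[str]
    cq_mean: np.ndarray  # (n_genes, n_samples)
    rep_sd: np.ndarray  # same shape; SD across contributing technical replicates

    def __post_init__(self) -> None:
        self.cq_mean = np.asarray(self.cq_mean, dtype=float)
        self.rep_sd = np.asarray(self.rep_sd, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cq_mean, index=self.genes, columns=self.samples)

    def subset(self, genes: list[str] | None = None, samples: list[str] | None = None) -> "CqMatrix":
        genes = list(self.genes) if genes is None else list(genes)
        samples = list(self.samples) if samples is None else list(samples)
        gi = [self.genes.index(g) for g in genes]
        si = [self.samples.index(s) for s in samples]
        return CqMatrix(genes, samples, self.cq_mean[np.ix_(gi, si)], self.rep_sd[np.ix_(gi, si)])


@dataclass
class GeneStats:
    """Descriptive Cq statistics for one gene across samples."""

    gene: str
    mean_cq: float
    min_cq: float
    max_cq: float
    cv_percent: float  # 100 * SD / mean, SD with n-1 denominator


@dataclass
class QCFlag:
    """A gene x observation cell whose technical-replicate SD exceeded the threshold."""

    gene: str
    observation: str
    sd: float
    mean: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sample_sheet(sheet_path) -> dict[str, SampleRecord]:
    """Read the sample sheet CSV.

    Columns: ``observation_id, sample_id, bio_rep, set_memberships, group,
    is_control`` where set_memberships is semicolon-separated.
    """
    sheet = pd.read_csv(sheet_path, dtype=str).fillna("")
    required = {"observation_id", "sample_id", "bio_rep", "set_memberships", "group", "is_control"}
    missing = required - set(sheet.columns)
    if missing:
        raise CqValidationError(f"sample sheet missing columns: {sorted(missing)}")
    records: dict[str, SampleRecord] = {}
    for _, row in sheet.iterrows():
        obs = row["observation_id"]
        if obs in records:
            raise CqValidationError(f"duplicate observation_id {obs!r} in sample sheet")
        sets = frozenset(s.strip() for s in row["set_memberships"].split(";") if s.strip())
        records[obs] = SampleRecord(
            sample_id=row["sample_id"],
            biological_replicate_id=row["bio_rep"],
            set_memberships=sets,
            group_label=row["group"],
            is_control=str(row["is_control"]).strip().lower() in {"1", "true", "yes"},
        )
    return records


def read_cq_table(path, sheet_path) -> CqDataset:
    """Read a wide Cq CSV (rows = genes, columns = ``<observation>_t<rep>``).

    Empty cells become NaN (missing), never zero.  Every column must be mapped
    by the sample sheet; unmapped columns and out-of-range Cq values are hard
    errors naming the offender.
    """
    table = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if table.shape[0] == 0:
        raise CqValidationError("no genes parsed")
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise CqValidationError(f"duplicate gene identifier {dup!r}")
    sample_sheet = read_sample_sheet(sheet_path)

    # parse column names into (observation, tech rep index)
    obs_order: dict[str, None] = {}
    col_map: list[tuple[str, int]] = []
    for col in table.columns:
        obs, sep, rep = col.rpartition("_t")
        if not sep or not rep.isdigit():
            raise CqValidationError(f"column {col!r} not of the form <observation>_t<rep>")
        if obs not in sample_sheet:
            raise CqValidationError(f"column {col!r}: observation {obs!r} not in sample sheet")
        obs_order.setdefault(obs, None)
        col_map.append((obs, int(rep)))

    observations = list(obs_order)
    n_reps = max(r for _, r in col_map)
    genes = [str(g) for g in table.index]
    cq = np.full((len(genes), len(observations), n_reps), np.nan)
    obs_idx = {o: i for i, o in enumerate(observations)}
    for j, (obs, rep) in enumerate(col_map):
        cq[:, obs_idx[obs], rep - 1] = pd.to_numeric(table.iloc[:, j], errors="coerce").to_numpy()

    sheet = {o: sample_sheet[o] for o in observations}
    return CqDataset(genes=genes, observations=observations, cq=cq, sample_sheet=sheet)


def write_cq_table(d: CqDataset, path, sheet_path) -> None:
    """Write a CqDataset back to the wide CSV + sample sheet pair read_cq_table reads."""
    n_reps = d.cq.shape[2]
    cols, data = [], []
    for i, obs in enumerate(d.observations):
        for r in range(n_reps):
            cols.append(f"{obs}_t{r + 1}")
            data.append(d.cq[:, i, r])
    pd.DataFrame(np.column_stack(data), index=pd.Index(d.genes, name="gene"), columns=cols).to_csv(path)

    rows = []
    for obs in d.observations:
        rec = d.sample_sheet[obs]
        rows.append(
            {
                "observation_id": obs,
                "sample_id": rec.sample_id,
                "bio_rep": rec.biological_replicate_id,
                "set_memberships": ";".join(sorted(rec.set_memberships)),
                "group": rec.group_label,
                "is_control": int(rec.is_control),
            }
        )
    pd.DataFrame(rows).to_csv(sheet_path, index=False)


# ---------------------------------------------------------------------------
# Aggregation and descriptive statistics
# ---------------------------------------------------------------------------

def aggregate_replicates(
    d: CqDataset, sd_flag_threshold: float = 0.5
) -> tuple[CqMatrix, list[QCFlag]]:
    """Average technical replicates per observation, then biological replicates
    per sample.

    Cells whose technical-replicate SD exceeds ``sd_flag_threshold`` cycles are
    flagged in the returned QC list but kept.  A gene x sample cell with no
    non-missing replicate at all becomes NaN with a warning.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices handled below
        obs_mean = np.nanmean(d.cq, axis=2)  # (genes, observations)
        obs_sd = np.nanstd(d.cq, axis=2, ddof=1)

    flags: list[QCFlag] = []
    for g, o in zip(*np.nonzero(np.nan_to_num(obs_sd) > sd_flag_threshold)):
        flags.append(QCFlag(d.genes[g], d.observations[o], float(obs_sd[g, o]), float(obs_mean[g, o])))

    samples = d.sample_ids
    sample_idx = {s: i for i, s in enumerate(samples)}
    groups: list[list[int]] = [[] for _ in samples]
    for i, obs in enumerate(d.observations):
        groups[sample_idx[d.sample_sheet[obs].sample_id]].append(i)

    n_g, n_s = len(d.genes), len(samples)
    cq_mean = np.full((n_g, n_s), np.nan)
    rep_sd = np.full((n_g, n_s), np.nan)
    for s, idx in enumerate(groups):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cq_mean[:, s] = np.nanmean(obs_mean[:, idx], axis=1)
            # spread of all raw technical replicates contributing to the cell
            raw = d.cq[:, idx, :].reshape(n_g, -1)
            cnt = np.sum(np.isfinite(raw), axis=1)
            sd = np.nanstd(raw, axis=1, ddof=1)
            rep_sd[:, s] = np.where(cnt > 1, sd, 0.0)
            rep_sd[cnt == 0, s] = np.nan

    for g, s in zip(*np.nonzero(~np.isfinite(cq_mean))):
        warnings.warn(
            f"gene {d.genes[g]} x sample {samples[s]}: no non-missing replicate; cell left missing",
            stacklevel=2,
        )
    return CqMatrix(list(d.genes), samples, cq_mean, rep_sd), flags


def descriptive_stats(m: CqMatrix) -> list[GeneStats]:
    """Per-gene mean, min, max and CV% of mean Cq across samples.

    CV uses the sample SD (n-1).  Genes with all-missing Cq are excluded with
    a warning; genes need at least two observed samples.
    """
    out: list[GeneStats] = []
    for g, gene in enumerate(m.genes):
        row = m.cq_mean[g]
        row = row[np.isfinite(row)]
        if row.size == 0:
            warnings.warn(f"gene {gene}: all Cq missing; excluded from descriptive stats", stacklevel=2)
            continue
        if row.size < 2:
            raise CqValidationError(f"gene {gene}: need >=2 samples for descriptive stats")
        mean = float(np.mean(row))
        sd = float(np.std(row, ddof=1))
        out.append(
            GeneStats(
                gene=gene,
                mean_cq=mean,
                min_cq=float(np.min(row)),
                max_cq=float(np.max(row)),
                cv_percent=100.0 * sd / mean,
            )
        )
    return out


def stats_to_frame(stats: list[GeneStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": s.gene, "mean_cq": s.mean_cq, "min_cq": s.min_cq, "max_cq": s.max_cq, "cv_percent": s.cv_percent}
            for s in stats
        ]
    ).set_index("gene")
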