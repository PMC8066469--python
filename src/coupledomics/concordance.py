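"""Read-vs-PSM concordance: library normalization, temporal deltas, OLS
regression, per-taxon activity bias, and cross-layer presence/absence.

The central quantity is the library-normalized relative abundance
r_{f,s} = c_{f,s} / sum_g c_{g,s} (reads or PSMs for feature f over the
library total).  Temporal plots use first-zeroed deltas: the first observed
time point is set to 0 and subsequent points are r_n - r_{n-1} over
consecutive observed days, so the deltas telescope to r_last - r_first.

Concordance between layers is an ordinary least-squares fit of PSM ratios
(y) on read ratios (x) for one (day, treatment), summarized by R².  A
taxon's activity bias is log2 of its smoothed PSM share over its smoothed
read share: positive means more metabolically active than presence predicts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import CountTable, SampleMeta, ValidationError

__all__ = [
    "RelativeAbundanceSeries",
    "ConcordanceResult",
    "normalize_library",
    "temporal_deltas",
    "delta_frame",
    "paired_concordance",
    "activity_bias",
    "cross_layer_presence",
    "pool_by_condition",
    "concordance_by_condition",
]

DEFAULT_PSEUDO = 1e-6

PRESENCE_STATES = ("both", "metagenome_only", "metaproteome_only", "neither")


@dataclass(frozen=True)
class RelativeAbundanceSeries:
    """Time-ordered library-normalized ratios and first-zeroed deltas for one feature."""

    feature_id: str
    treatment: str
    days: tuple[int, ...]
    ratios: tuple[float, ...]
    deltas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.ratios) or len(self.days) != len(self.deltas):
            raise ValidationError("days, ratios and deltas must have equal length")
        if self.deltas and self.deltas[0] != 0.0:
            raise ValidationError("first delta must be 0")


@dataclass(frozen=True)
class ConcordanceResult:
    """OLS summary for one (day, treatment) read-vs-PSM regression."""

    day: int
    treatment: str
    feature_kind: str
    n_features: int
    slope: float
    intercept: float
    r_squared: float


def normalize_library(table: CountTable) -> CountTable:
    """Divide each sample column by its own total so columns sum to 1."""
    totals = table.data.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"all-zero sample column(s): {zero}")
    return table.with_data(table.data / totals)


def delta_frame(ratios: pd.DataFrame, day_order: Sequence[int]) -> pd.DataFrame:
    """First-zeroed consecutive differences of a feature x day ratio frame.

    Day columns absent from ``ratios`` but listed in ``day_order`` are
    treated as ratio 0 (absence is informative in count data).  Columns not
    in ``day_order`` are an error, as are duplicated days.
    """
    days = list(day_order)
    if len(set(days)) != len(days):
        raise ValidationError(f"duplicate day in day order: {days}")
    extra = [c for c in ratios.columns if c not in days]
    if extra:
        raise ValidationError(f"day column(s) {extra} not in configured day order {days}")
    if ratios.columns.duplicated().any():
        raise ValidationError("duplicate day column for one series")
    observed = [d for d in days if d in set(ratios.columns)]
    if not observed:
        raise ValidationError("no observed days")
    filled = ratios.reindex(columns=observed).astype(float)
    deltas = filled.diff(axis=1)
    deltas[observed[0]] = 0.0
    return deltas


def temporal_deltas(
    ratios: pd.DataFrame, day_order: Sequence[int], treatment: str = ""
) -> list[RelativeAbundanceSeries]:
    """Per-feature first-zeroed delta series over the observed days."""
    deltas = delta_frame(ratios, day_order)
    observed = list(deltas.columns)
    filled = ratios.reindex(columns=observed).astype(float)
    return [
        RelativeAbundanceSeries(
            feature_id=str(f),
            treatment=treatment,
            days=tuple(int(d) for d in observed),
            ratios=tuple(filled.loc[f].tolist()),
            deltas=tuple(deltas.loc[f].tolist()),
        )
        for f in ratios.index
    ]


def paired_concordance(
    read_values: pd.Series | Sequence[float],
    psm_values: pd.Series | Sequence[float],
    day: int = 0,
    treatment: str = "",
    feature_kind: str = "taxon",
) -> ConcordanceResult:
    """OLS of PSM values (y) on read values (x), paired by feature id.

    R² = 1 - SS_res/SS_tot; when SS_tot == 0 (constant y) it is defined as 1
    if the fit is exact and 0 otherwise.
    """
    if isinstance(read_values, pd.Series) and isinstance(psm_values, pd.Series):
        only_reads = set(read_values.index) - set(psm_values.index)
        only_psms = set(psm_values.index) - set(read_values.index)
        if only_reads or only_psms:
            raise ValidationError(
                "mismatched feature sets; "
                f"only in reads: {sorted(only_reads)}; only in PSMs: {sorted(only_psms)}"
            )
        psm_values = psm_values.reindex(read_values.index)
    x = np.asarray(read_values, dtype=float)
    y = np.asarray(psm_values, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError(f"need at least 2 paired features, got {x.size}")
    if np.ptp(x) == 0:
        raise ValidationError("read values are constant; slope undefined")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        # constant y: nothing to explain, no concordance signal
        r_squared = 0.0
    else:
        r_squared = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return ConcordanceResult(
        day=day,
        treatment=treatment,
        feature_kind=feature_kind,
        n_features=int(x.size),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
    )


def activity_bias(read_ratio: float, psm_ratio: float, pseudo: float = DEFAULT_PSEUDO) -> float:
    """log2((psm_ratio + pseudo) / (read_ratio + pseudo)).

    Positive: the taxon is more metabolically active than its genomic
    presence predicts; negative: less.  Exactly equal ratios return exactly 0.
    """
    if pseudo <= 0:
        raise ValueError(f"pseudo must be positive, got {pseudo}")
    for name, v in (("read_ratio", read_ratio), ("psm_ratio", psm_ratio)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if read_ratio == psm_ratio:
        return 0.0
    return math.log2((psm_ratio + pseudo) / (read_ratio + pseudo))


def pool_by_condition(
    table: CountTable, meta: Sequence[SampleMeta]
) -> pd.DataFrame:
    """Sum counts within each (day, treatment), matching columns to metadata.

    Columns are matched by sample_id first, then by technical-replicate group
    id (so already-averaged proteomics tables pool correctly).  Returns a
    feature x MultiIndex[(day, treatment)] frame.
    """
    by_sample = {m.sample_id: m for m in meta if m.layer == table.layer}
    by_group: dict[str, SampleMeta] = {}
    for m in by_sample.values():
        if m.tech_replicate_group:
            by_group.setdefault(m.tech_replicate_group, m)
    pooled: dict[tuple[int, str], pd.Series] = {}
    for col in table.samples:
        m = by_sample.get(col) or by_group.get(col)
        if m is None:
            raise ValidationError(f"sample {col!r} not found in {table.layer} metadata")
        key = (m.day, m.treatment)
        col_counts = table.data[col]
        pooled[key] = pooled[key] + col_counts if key in pooled else col_counts.astype(float)
    out = pd.DataFrame(pooled)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["day", "treatment"])
    return out


def cross_layer_presence(
    metagenome: CountTable,
    metaproteome: CountTable,
    meta: Sequence[SampleMeta],
) -> pd.DataFrame:
    """Classify each feature at each shared (day, treatment) into
    both / metagenome_only / metaproteome_only / neither.

    Features absent from one table's feature list count as 0 in that layer.
    """
    reads = pool_by_condition(metagenome, meta)
    psms = pool_by_condition(metaproteome, meta)
    shared = [k for k in reads.columns if k in set(psms.columns)]
    if not shared:
        raise ValidationError("no overlapping (day, treatment) keys between layers")
    features = sorted(set(metagenome.features) | set(metaproteome.features))
    reads = reads.reindex(index=features, columns=shared, fill_value=0.0).fillna(0.0)
    psms = psms.reindex(index=features, columns=shared, fill_value=0.0).fillna(0.0)
    r = reads.to_numpy() > 0
    p = psms.to_numpy() > 0
    states = np.where(
        r & p, "both", np.where(r, "metagenome_only", np.where(p, "metaproteome_only", "neither"))
    )
    return pd.DataFrame(states, index=features, columns=pd.MultiIndex.from_tuples(shared, names=["day", "treatment"]))


def concordance_by_condition(
    metagenome: CountTable,
    metaproteome: CountTable,
    meta: Sequence[SampleMeta],
    feature_kind: str = "taxon",
    use_deltas: bool = False,
    day_order: Sequence[int] | None = None,
) -> list[ConcordanceResult]:
    """One read-vs-PSM OLS per shared (day, treatment).

    By default regresses per-condition normalized ratios; with
    ``use_deltas`` the per-interval deltas are regressed instead.  Features
    missing in one layer are zero-filled before regression.
    """
    reads = pool_by_condition(metagenome, meta)
    psms = pool_by_condition(metaproteome, meta)
    shared = [k for k in reads.columns if k in set(psms.columns)]
    if not shared:
        raise ValidationError("no overlapping (day, treatment) keys between layers")
    features = sorted(set(metagenome.features) | set(metaproteome.features))
    reads = reads.reindex(index=features, columns=shared, fill_value=0.0).fillna(0.0)
    psms = psms.reindex(index=features, columns=shared, fill_value=0.0).fillna(0.0)
    read_ratios = reads / reads.sum(axis=0)
    psm_ratios = psms / psms.sum(axis=0)
    if use_deltas:
        if day_order is None:
            day_order = sorted({d for d, _ in shared})
        treatments = sorted({t for _, t in shared})
        read_by_t = {}
        psm_by_t = {}
        for t in treatments:
            cols = [d for d, tt in shared if tt == t]
            rsub = read_ratios.loc[:, [(d, t) for d in cols]]
            rsub.columns = cols
            psub = psm_ratios.loc[:, [(d, t) for d in cols]]
            psub.columns = cols
            read_by_t[t] = delta_frame(rsub, day_order)
            psm_by_t[t] = delta_frame(psub, day_order)
        read_ratios = pd.concat(
            {t: read_by_t[t] for t in treatments}, axis=1
        ).swaplevel(axis=1)
        psm_ratios = pd.concat({t: psm_by_t[t] for t in treatments}, axis=1).swaplevel(axis=1)
        # first observed day per treatment carries all-zero deltas by
        # construction; no regression is defined there
        first_days = {t: min(d for d, tt in shared if tt == t) for t in treatments}
        shared = [(d, t) for d, t in shared if d != first_days[t]]
        if not shared:
            raise ValidationError("delta regression needs at least two observed days")
    results = []
    for day, treatment in shared:
        results.append(
            paired_concordance(
                read_ratios[(day, treatment)],
                psm_ratios[(day, treatment)],
                day=int(day),
                treatment=str(treatment),
                feature_kind=feature_kind,
            )
        )
    return results
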