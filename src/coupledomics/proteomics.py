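"""Protein-evidence filtering, replicate averaging, NSAF, and PSM aggregation.

The evidence filter keeps proteins with at least ``min_unique`` unique
peptides (pooled across all runs) and a ProteinProphet-style probability at
or above ``min_probability``; the defaults (2, 0.93) correspond to a 1% FDR
in an Abacus combined file.

NSAF (normalized spectral abundance factor) for protein *i* in sample *s* is

    NSAF_{i,s} = (SpC_{i,s} / L_i) / sum_j (SpC_{j,s} / L_j)

with SpC the spectral count and L the protein length in amino acids, so each
sample column sums to 1.

Replicate averaging happens on raw spectral counts before NSAF and before
library normalization — averaging normalized values would weight runs with
fewer total PSMs more heavily.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import (
    RANKS,
    UNASSIGNED,
    AnnotationMap,
    CountTable,
    ProteinRecord,
    SampleMeta,
    ValidationError,
)

__all__ = [
    "ProteinRecord",
    "filter_proteins",
    "protein_count_table",
    "average_technical_replicates",
    "compute_nsaf",
    "aggregate_psms",
]

DEFAULT_MIN_UNIQUE = 2
DEFAULT_MIN_PROBABILITY = 0.93


def filter_proteins(
    records: Sequence[ProteinRecord],
    min_unique: int = DEFAULT_MIN_UNIQUE,
    min_probability: float = DEFAULT_MIN_PROBABILITY,
) -> list[ProteinRecord]:
    """Keep records with ``unique_peptides >= min_unique`` and
    ``probability >= min_probability``; order preserved, input untouched."""
    if min_unique < 0:
        raise ValueError(f"min_unique must be nonnegative, got {min_unique}")
    if not 0.0 <= min_probability <= 1.0:
        raise ValueError(f"min_probability must be in [0, 1], got {min_probability}")
    return [
        r
        for r in records
        if r.unique_peptides >= min_unique and r.probability >= min_probability
    ]


def protein_count_table(records: Sequence[ProteinRecord]) -> CountTable:
    """Assemble a protein x run spectral-count table from records."""
    if not records:
        raise ValidationError("no protein records to tabulate")
    run_ids = list(records[0].spectral_counts)
    for rec in records:
        if list(rec.spectral_counts) != run_ids:
            raise ValidationError(
                f"protein {rec.protein_id!r} has a different run set than the first record"
            )
    data = pd.DataFrame(
        [[rec.spectral_counts[r] for r in run_ids] for rec in records],
        index=[rec.protein_id for rec in records],
        columns=run_ids,
    )
    return CountTable(data=data, layer="metaproteome", feature_kind="protein")


def average_technical_replicates(
    table: CountTable, meta: Sequence[SampleMeta]
) -> CountTable:
    """Collapse technical-replicate runs to one column per replicate group.

    Each output cell is the arithmetic mean of that group's runs, so values
    may be non-integer.  The operation is idempotent: columns already named
    by a replicate-group id pass through unchanged.
    """
    by_sample = {m.sample_id: m for m in meta if m.layer == "metaproteome"}
    group_ids = {m.tech_replicate_group for m in by_sample.values()}
    col_group: dict[str, str] = {}
    for col in table.samples:
        if col in by_sample:
            col_group[col] = by_sample[col].tech_replicate_group  # type: ignore[assignment]
        elif col in group_ids:
            col_group[col] = col  # already averaged
        else:
            raise ValidationError(
                f"run {col!r} has no technical-replicate group in the metadata"
            )
    order: list[str] = []
    members: dict[str, list[str]] = {}
    for col in table.samples:
        g = col_group[col]
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(col)
    for g, cols in members.items():
        if not cols:
            raise ValidationError(f"replicate group {g!r} has zero member runs")
    data = pd.DataFrame(
        {g: table.data[members[g]].mean(axis=1) for g in order}, index=table.data.index
    )
    return table.with_data(data)


def compute_nsaf(table: CountTable, lengths: Mapping[str, int]) -> CountTable:
    """Length-normalize spectral counts and scale each sample column to sum 1.

    Raises if any sample has no nonzero counts (NSAF undefined) or a protein
    is missing a length.
    """
    if table.feature_kind != "protein":
        raise ValidationError("NSAF is defined on a protein-level table")
    missing = [p for p in table.features if p not in lengths]
    if missing:
        raise ValidationError(f"missing length for protein(s): {missing[:5]}")
    lvec = np.array([lengths[p] for p in table.features], dtype=float)
    if (lvec <= 0).any():
        bad = [p for p, l in zip(table.features, lvec) if l <= 0]
        raise ValidationError(f"non-positive length for protein(s): {bad}")
    saf = table.data.to_numpy(dtype=float) / lvec[:, None]
    colsum = saf.sum(axis=0)
    zero = np.nonzero(colsum == 0)[0]
    if zero.size:
        raise ValidationError(
            f"sample(s) with all-zero spectral counts: {[table.samples[i] for i in zero]}"
        )
    nsaf = pd.DataFrame(saf / colsum, index=table.data.index, columns=table.data.columns)
    return CountTable(data=nsaf, layer="metaproteome", feature_kind="protein")


def lineage_label(lineage: Sequence[str], rank: str) -> str:
    """Taxon label for a lineage at the requested rank.

    A lineage that stops above the requested rank is reported at its deepest
    available rank (mixed Kingdom-through-Class reporting); an empty lineage
    maps to the "unassigned" bucket.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if not lineage:
        return UNASSIGNED
    idx = RANKS.index(rank)
    return lineage[min(idx, len(lineage) - 1)]


def aggregate_psms(
    table: CountTable,
    ann: AnnotationMap,
    level: str = "taxon",
    rank: str = "Class",
) -> CountTable:
    """Aggregate a protein-level count table to taxa or GO terms.

    Taxon mode adds each protein's counts to its lineage entry at ``rank``
    (or the deepest available shallower rank).  GO mode adds each protein's
    counts to EVERY GO term it carries — one PSM may count toward multiple
    terms, so term totals are not spectrum totals.  Proteins with no mapping
    accumulate under "unassigned".  Taxon aggregation conserves mass:
    summing over taxa (including "unassigned") returns the protein totals.
    """
    if table.feature_kind != "protein":
        raise ValidationError("aggregation requires a protein-level table")
    if level not in ("taxon", "go_term"):
        raise ValueError(f"unknown aggregation level {level!r}")
    counts = table.data
    out: dict[str, np.ndarray] = {}

    def add(feature: str, values: np.ndarray) -> None:
        if feature in out:
            out[feature] = out[feature] + values
        else:
            out[feature] = values.astype(float).copy()

    for pid in table.features:
        values = counts.loc[pid].to_numpy(dtype=float)
        if level == "taxon":
            add(lineage_label(ann.lineages.get(pid, ()), rank), values)
        else:
            terms = ann.go_terms.get(pid, frozenset())
            if not terms:
                add(UNASSIGNED, values)
            else:
                for term in sorted(terms):
                    add(term, values)
    data = pd.DataFrame.from_dict(out, orient="index", columns=counts.columns)
    data = data.sort_index()
    return CountTable(data=data, layer=table.layer, feature_kind=level)
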