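"""Differential GO-term abundance between (day, treatment) conditions.

For a term with pooled PSM count k out of library total N in each of two
conditions, the statistic is the log2 ratio of Laplace-smoothed proportions

    log2( ((k_b + pseudo) / (N_b + pseudo)) / ((k_a + pseudo) / (N_a + pseudo)) )

tested with a two-proportion z-test on the smoothed proportions and corrected
across terms with Benjamini-Hochberg; a term is called significant when its
q-value is at or below alpha (default 0.05).  Comparisons run for all
consecutive-day pairs within a treatment and both-treatment pairs within a
day.  By default only prokaryote-annotated proteins (Kingdom Bacteria or
Archaea) enter the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .io_tables import UNASSIGNED, AnnotationMap, CountTable, SampleMeta, ValidationError
from .proteomics import aggregate_psms, lineage_label

__all__ = [
    "GoDifferentialResult",
    "TaxonContribution",
    "pool_condition",
    "go_ratio_test",
    "correct_qvalues",
    "run_go_differential",
    "taxon_contributions",
]

DEFAULT_PSEUDO = 1.0
DEFAULT_ALPHA = 0.05
PROKARYOTE_KINGDOMS = frozenset({"Bacteria", "Archaea"})


@dataclass(frozen=True)
class GoDifferentialResult:
    go_term: str
    condition_a: str
    condition_b: str
    psm_a: float
    psm_b: float
    total_a: float
    total_b: float
    log2_ratio: float
    p_value: float
    q_value: float
    significant: bool


@dataclass(frozen=True)
class TaxonContribution:
    go_term: str
    taxon: str
    condition: str
    fraction: float


def _match_columns(table: CountTable, meta: Sequence[SampleMeta]) -> dict[str, SampleMeta]:
    by_sample = {m.sample_id: m for m in meta if m.layer == table.layer}
    by_group: dict[str, SampleMeta] = {}
    for m in by_sample.values():
        if m.tech_replicate_group:
            by_group.setdefault(m.tech_replicate_group, m)
    out = {}
    for col in table.samples:
        m = by_sample.get(col) or by_group.get(col)
        if m is None:
            raise ValidationError(f"sample {col!r} not found in {table.layer} metadata")
        out[col] = m
    return out


def pool_condition(
    table: CountTable, meta: Sequence[SampleMeta], condition: tuple[int, str]
) -> pd.Series:
    """Per-feature arithmetic mean across the samples of one (day, treatment).

    Pooling by mean (after technical-replicate averaging) yields the single
    per-condition profile that the pairwise tests consume.
    """
    day, treatment = condition
    col_meta = _match_columns(table, meta)
    cols = [c for c, m in col_meta.items() if m.day == day and m.treatment == treatment]
    if not cols:
        raise ValidationError(f"no samples match condition (day={day}, treatment={treatment!r})")
    return table.data[cols].mean(axis=1)


def go_ratio_test(
    psm_a: float, total_a: float, psm_b: float, total_b: float, pseudo: float = DEFAULT_PSEUDO
) -> tuple[float, float]:
    """Laplace-smoothed log2 proportion ratio (b over a) and two-sided p-value.

    The z-test uses the pooled smoothed proportion; swapping conditions
    negates the log2 ratio and leaves the p-value unchanged.
    """
    if pseudo <= 0:
        raise ValueError(f"pseudo must be positive, got {pseudo}")
    for name, total, psm in (("a", total_a, psm_a), ("b", total_b, psm_b)):
        if total <= 0:
            raise ValidationError(f"condition {name}: library total must be positive, got {total}")
        if psm < 0 or psm > total:
            raise ValidationError(
                f"condition {name}: PSM count {psm} outside [0, total={total}]"
            )
    pa = (psm_a + pseudo) / (total_a + pseudo)
    pb = (psm_b + pseudo) / (total_b + pseudo)
    log2_ratio = math.log2(pb / pa)
    pooled = (psm_a + psm_b + 2 * pseudo) / (total_a + total_b + 2 * pseudo)
    se = math.sqrt(
        pooled * (1 - pooled) * (1 / (total_a + pseudo) + 1 / (total_b + pseudo))
    )
    if se == 0.0:
        return log2_ratio, 1.0
    z = (pb - pa) / se
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return log2_ratio, max(p, 1e-300)


def correct_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        bad = p[(p <= 0) | (p > 1)]
        raise ValueError(f"p-values outside (0, 1]: {bad.tolist()}")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def default_comparisons(
    meta: Sequence[SampleMeta], day_order: Sequence[int] | None = None
) -> list[tuple[tuple[int, str], tuple[int, str]]]:
    """Consecutive-day pairs within each treatment plus treatment pairs within each day."""
    conds = sorted({(m.day, m.treatment) for m in meta if m.layer == "metaproteome"})
    days = sorted({d for d, _ in conds}) if day_order is None else [d for d in day_order if any(c[0] == d for c in conds)]
    treatments = sorted({t for _, t in conds})
    pairs = []
    for t in treatments:
        observed = [d for d in days if (d, t) in conds]
        pairs.extend([((d1, t), (d2, t)) for d1, d2 in zip(observed, observed[1:])])
    for d in days:
        present = [t for t in treatments if (d, t) in conds]
        pairs.extend(
            [((d, t1), (d, t2)) for i, t1 in enumerate(present) for t2 in present[i + 1 :]]
        )
    return pairs


def _prokaryote_ids(table: CountTable, ann: AnnotationMap) -> list[str]:
    return [
        p
        for p in table.features
        if ann.lineages.get(p) and ann.lineages[p][0] in PROKARYOTE_KINGDOMS
    ]


def run_go_differential(
    protein_table: CountTable,
    ann: AnnotationMap,
    meta: Sequence[SampleMeta],
    alpha: float = DEFAULT_ALPHA,
    pseudo: float = DEFAULT_PSEUDO,
    prokaryote_only: bool = True,
    day_order: Sequence[int] | None = None,
) -> pd.DataFrame:
    """All pairwise GO-term tests, BH-corrected within each comparison.

    Library totals are total (prokaryote) protein-level PSMs per condition,
    not sums over GO terms — multi-assignment double-counts PSMs across
    terms, so term sums exceed spectrum totals by construction.
    """
    if prokaryote_only:
        keep = _prokaryote_ids(protein_table, ann)
        if not keep:
            raise ValidationError("no prokaryote-annotated proteins in the table")
        protein_table = protein_table.with_data(protein_table.data.loc[keep])
    go_table = aggregate_psms(protein_table, ann, level="go_term")
    go_table = go_table.with_data(go_table.data.drop(index=UNASSIGNED, errors="ignore"))
    rows = []
    for cond_a, cond_b in default_comparisons(meta, day_order):
        term_a = pool_condition(go_table, meta, cond_a)
        term_b = pool_condition(go_table, meta, cond_b)
        total_a = float(pool_condition(protein_table, meta, cond_a).sum())
        total_b = float(pool_condition(protein_table, meta, cond_b).sum())
        stats = [
            go_ratio_test(float(term_a[g]), total_a, float(term_b[g]), total_b, pseudo)
            for g in go_table.features
        ]
        pvals = [p for _, p in stats]
        qvals = correct_qvalues(pvals)
        label_a = f"day{cond_a[0]}_{cond_a[1]}"
        label_b = f"day{cond_b[0]}_{cond_b[1]}"
        for g, (lr, p), q in zip(go_table.features, stats, qvals):
            rows.append(
                GoDifferentialResult(
                    go_term=g,
                    condition_a=label_a,
                    condition_b=label_b,
                    psm_a=float(term_a[g]),
                    psm_b=float(term_b[g]),
                    total_a=total_a,
                    total_b=total_b,
                    log2_ratio=lr,
                    p_value=p,
                    q_value=float(q),
                    significant=bool(q <= alpha),
                )
            )
    import dataclasses

    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def taxon_contributions(
    protein_table: CountTable,
    ann: AnnotationMap,
    go_term: str,
    condition: tuple[int, str],
    meta: Sequence[SampleMeta],
    rank: str = "Class",
) -> list[TaxonContribution]:
    """Per-taxon share of one GO term's pooled PSMs in one condition.

    Shares sum to 1; taxa follow the mixed Kingdom-through-Class convention.
    """
    pooled = pool_condition(protein_table, meta, condition)
    shares: dict[str, float] = {}
    for pid, count in pooled.items():
        if go_term in ann.go_terms.get(pid, frozenset()) and count > 0:
            taxon = lineage_label(ann.lineages.get(pid, ()), rank)
            shares[taxon] = shares.get(taxon, 0.0) + float(count)
    total = sum(shares.values())
    if total <= 0:
        raise ValidationError(
            f"GO term {go_term!r} has no attributed PSMs in condition {condition}"
        )
    label = f"day{condition[0]}_{condition[1]}"
    return [
        TaxonContribution(go_term=go_term, taxon=t, condition=label, fraction=c / total)
        for t, c in sorted(shares.items())
    ]
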