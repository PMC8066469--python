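"""Synthetic coupled metagenome/metaproteome generator with known ground truth.

The generator emulates a hatchery-water microbiome study design: two pH
treatments (7.1, 8.2) sampled on days 1, 5, 8 and 12, ~25 taxonomic groups
with mixed Kingdom-through-Class labels, metagenomic read counts and
metaproteomic PSM counts drawn multinomially from coupled proportion
vectors, and triplicate technical injections per proteomics sample.

Coupling model: reads are drawn from per-condition taxon proportions
p_t(day, treatment); PSMs are drawn from the activity-distorted proportions

    q_t = p_t * a_t / sum_u p_u * a_u

where a_t > 0 is the taxon's activity multiplier (a_t = 1 for all t makes
the layers concordant).  PSMs land on a taxon's proteins proportionally to
length x expression share and are split multinomially across technical
replicates.  Taxa in a dropout set get structural zeros in one layer,
mimicking taxa detected by sequencing but never by mass spectrometry.

Day-to-day trajectories are piecewise-constant with multiplicative jumps
(bloom-like shifts) rather than a parametric dynamic model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concordance import (
    ConcordanceResult,
    activity_bias,
    concordance_by_condition,
    cross_layer_presence,
)
from .io_tables import (
    AnnotationMap,
    CountTable,
    ProteinRecord,
    SampleMeta,
    ValidationError,
)

__all__ = [
    "DEFAULT_TAXA",
    "SimulationConfig",
    "SimulationTruth",
    "SimulationResult",
    "RecoveryReport",
    "simulate",
    "recovery_report",
]

#: Mixed Kingdom-through-Class taxonomic groups with their lineages; the mix
#: of ranks mirrors LCA-style assignment where many reads/proteins resolve
#: only to phylum or kingdom.
DEFAULT_TAXA: dict[str, tuple[str, ...]] = {
    "Alphaproteobacteria": ("Bacteria", "Proteobacteria", "Alphaproteobacteria"),
    "Betaproteobacteria": ("Bacteria", "Proteobacteria", "Betaproteobacteria"),
    "Gammaproteobacteria": ("Bacteria", "Proteobacteria", "Gammaproteobacteria"),
    "Deltaproteobacteria": ("Bacteria", "Proteobacteria", "Deltaproteobacteria"),
    "Epsilonproteobacteria": ("Bacteria", "Proteobacteria", "Epsilonproteobacteria"),
    "Flavobacteriia": ("Bacteria", "Bacteroidetes", "Flavobacteriia"),
    "Cytophagia": ("Bacteria", "Bacteroidetes", "Cytophagia"),
    "Sphingobacteriia": ("Bacteria", "Bacteroidetes", "Sphingobacteriia"),
    "Bacteroidia": ("Bacteria", "Bacteroidetes", "Bacteroidia"),
    "Gloeobacteria": ("Bacteria", "Cyanobacteria", "Gloeobacteria"),
    "Nostocales": ("Bacteria", "Cyanobacteria", "Nostocales"),
    "Acidimicrobiia": ("Bacteria", "Actinobacteria", "Acidimicrobiia"),
    "Actinomycetia": ("Bacteria", "Actinobacteria", "Actinomycetia"),
    "Verrucomicrobiae": ("Bacteria", "Verrucomicrobia", "Verrucomicrobiae"),
    "Planctomycetia": ("Bacteria", "Planctomycetes", "Planctomycetia"),
    "Bacilli": ("Bacteria", "Firmicutes", "Bacilli"),
    "Clostridia": ("Bacteria", "Firmicutes", "Clostridia"),
    "Proteobacteria": ("Bacteria", "Proteobacteria"),
    "Bacteroidetes": ("Bacteria", "Bacteroidetes"),
    "Cyanobacteria": ("Bacteria", "Cyanobacteria"),
    "Actinobacteria": ("Bacteria", "Actinobacteria"),
    "Verrucomicrobia": ("Bacteria", "Verrucomicrobia"),
    "candidate_division_NC10": ("Bacteria", "candidate_division_NC10"),
    "Bacteria": ("Bacteria",),
    "Archaea": ("Archaea",),
}

#: Default activity multipliers: over/under-active taxa chosen to emulate the
#: qualitative activity-bias pattern real coupled datasets show.
DEFAULT_ACTIVITY: dict[str, float] = {
    "Deltaproteobacteria": 4.0,
    "Alphaproteobacteria": 2.0,
    "Betaproteobacteria": 0.25,
    "Cytophagia": 0.5,
    "Gammaproteobacteria": 0.5,
    "Flavobacteriia": 0.5,
}

#: MEGAN-export-style GO category labels assignable to simulated proteins.
DEFAULT_GO_TERMS = (
    "transport",
    "intracellular part",
    "protein-chromophore linkage",
    "electron transport chain",
    "nucleotide binding",
    "catalytic activity",
    "anion binding",
    "oxidoreductase activity",
    "translation",
    "photosynthesis",
    "proteolysis",
    "ion transport",
    "ATP binding",
    "DNA binding",
    "membrane",
)

#: Taxa dominant in read abundance (weight boost applied to the baseline).
_DOMINANT_BOOST = {"Alphaproteobacteria": 8.0, "Gammaproteobacteria": 6.0, "Flavobacteriia": 4.0}

DEFAULT_DAYS = (1, 5, 8, 12)
DEFAULT_TREATMENTS = ("pH7.1", "pH8.2")


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic coupled-omics dataset.

    ``baseline`` holds the per-condition taxon proportion vectors p_t
    (taxa x (treatment, day) MultiIndex columns, each column summing to 1).
    """

    taxa: tuple[str, ...]
    lineages: dict[str, tuple[str, ...]]
    baseline: pd.DataFrame
    activity: pd.Series
    psm_dropout: frozenset[str] = frozenset()
    read_dropout: frozenset[str] = frozenset()
    n_reads: int = 1_000_000
    n_psm: int = 30_000
    days: tuple[int, ...] = DEFAULT_DAYS
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    tanks_per_treatment: int = 2
    tech_replicates: int = 3
    proteins_per_taxon: int = 5
    overdispersion: float | None = None
    seed: int = 0

    def violations(self) -> list[str]:
        out = []
        if len(set(self.taxa)) != len(self.taxa):
            out.append("duplicate taxon names")
        missing = [t for t in self.taxa if not self.lineages.get(t)]
        if missing:
            out.append(f"taxa without lineage: {missing}")
        for key in self.baseline.columns:
            s = self.baseline[key].sum()
            if abs(s - 1.0) > 1e-6:
                out.append(f"baseline proportions for {key} sum to {s}, not 1")
            if (self.baseline[key] < 0).any():
                out.append(f"negative baseline proportion in {key}")
        if (self.activity <= 0).any():
            out.append("activity multipliers must be positive")
        if self.n_reads < 1 or self.n_psm < 1:
            out.append("library sizes must be >= 1")
        if self.tech_replicates < 1:
            out.append("tech_replicates must be >= 1")
        if self.proteins_per_taxon < 1:
            out.append("proteins_per_taxon must be >= 1")
        if self.overdispersion is not None and self.overdispersion <= 0:
            out.append("overdispersion concentration must be positive")
        unknown = (self.psm_dropout | self.read_dropout) - set(self.taxa)
        if unknown:
            out.append(f"dropout taxa not in taxon list: {sorted(unknown)}")
        return out

    @classmethod
    def default(
        cls,
        seed: int = 0,
        taxa: Mapping[str, tuple[str, ...]] | None = None,
        activity: Mapping[str, float] | None = None,
        psm_dropout: Sequence[str] = ("Archaea", "candidate_division_NC10"),
        read_dropout: Sequence[str] = (),
        jump_sigma: float = 0.4,
        treatment_sigma: float = 0.15,
        **overrides,
    ) -> "SimulationConfig":
        """Build the study-shaped default configuration.

        Baseline abundances are log-normal weights (a few dominant taxa
        boosted).  Day-to-day trajectories are a shared multiplicative random
        walk of scale ``jump_sigma`` — both treatments draw from the same
        source water, so temporal bloom shifts dominate — plus a milder
        independent treatment jitter of scale ``treatment_sigma`` per
        condition.  Columns are normalized per condition; all randomness
        derives from ``seed``.
        """
        lineages = dict(taxa) if taxa is not None else dict(DEFAULT_TAXA)
        names = tuple(lineages)
        days = tuple(overrides.pop("days", DEFAULT_DAYS))
        treatments = tuple(overrides.pop("treatments", DEFAULT_TREATMENTS))
        rng = np.random.default_rng(seed)
        weights = np.exp(rng.normal(0.0, 1.5, size=len(names)))
        for t, boost in _DOMINANT_BOOST.items():
            if t in names:
                weights[names.index(t)] *= boost
        cols = {}
        w_day = weights
        for day in days:
            w_day = w_day * np.exp(rng.normal(0.0, jump_sigma, size=len(names)))
            for treatment in treatments:
                w = w_day * np.exp(rng.normal(0.0, treatment_sigma, size=len(names)))
                cols[(treatment, day)] = w / w.sum()
        baseline = pd.DataFrame(cols, index=list(names))
        baseline.columns = pd.MultiIndex.from_tuples(baseline.columns, names=["treatment", "day"])
        act = pd.Series(1.0, index=list(names))
        for t, a in (activity if activity is not None else DEFAULT_ACTIVITY).items():
            if t in act.index:
                act[t] = a
        return cls(
            taxa=names,
            lineages=lineages,
            baseline=baseline,
            activity=act,
            psm_dropout=frozenset(psm_dropout),
            read_dropout=frozenset(read_dropout),
            days=days,
            treatments=treatments,
            seed=seed,
            **overrides,
        )


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth layer proportions and distortion parameters.

    ``p`` are the read-layer proportions (after read-layer dropout zeros),
    ``q`` the PSM-layer proportions p*a renormalized after PSM dropout; both
    are taxa x (treatment, day) frames with columns summing to 1.
    """

    p: pd.DataFrame
    q: pd.DataFrame
    activity: pd.Series
    psm_dropout: frozenset[str]
    read_dropout: frozenset[str]

    def pooled_log2_bias(self) -> pd.Series:
        """log2(q̄_t / p̄_t) with condition-averaged shares; NaN for taxa
        absent from either layer."""
        p_bar = self.p.mean(axis=1)
        q_bar = self.q.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log2(q_bar / p_bar)
        return pd.Series(np.where((p_bar > 0) & (q_bar > 0), vals, np.nan), index=self.p.index)


@dataclass
class SimulationResult:
    metagenome_taxa: CountTable
    metagenome_go: CountTable
    proteins: list[ProteinRecord]
    protein_table: CountTable
    annotations: AnnotationMap
    meta: list[SampleMeta]
    truth: SimulationTruth
    config: SimulationConfig


def _condition_vector(config: SimulationConfig, treatment: str, day: int, layer: str) -> np.ndarray:
    p = config.baseline[(treatment, day)].to_numpy(dtype=float).copy()
    if layer == "metaproteome":
        p = p * config.activity.to_numpy(dtype=float)
        drop = config.psm_dropout
    else:
        drop = config.read_dropout
    for t in drop:
        p[config.taxa.index(t)] = 0.0
    total = p.sum()
    if total <= 0:
        raise ValidationError(f"condition ({day}, {treatment}): all taxa dropped in {layer}")
    return p / total


def _draw(rng: np.random.Generator, n: int, p: np.ndarray, overdispersion: float | None) -> np.ndarray:
    if overdispersion is not None:
        mask = p > 0
        alpha = overdispersion * p[mask]
        draw = np.zeros_like(p)
        draw[mask] = rng.dirichlet(alpha)
        p = draw
    return rng.multinomial(n, p)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Draw one coupled dataset; fully reproducible given ``config.seed``."""
    problems = config.violations()
    if problems:
        raise ValidationError("invalid simulation config: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed)
    n_taxa = len(config.taxa)

    # --- protein complement: lengths, expression shares, GO terms, scores
    protein_ids: list[str] = []
    protein_taxon: list[int] = []
    lengths: dict[str, int] = {}
    go_terms: dict[str, frozenset[str]] = {}
    lineages: dict[str, tuple[str, ...]] = {}
    weights_within: dict[int, np.ndarray] = {}
    for ti, taxon in enumerate(config.taxa):
        plens = rng.integers(100, 1001, size=config.proteins_per_taxon)
        shares = rng.dirichlet(np.ones(config.proteins_per_taxon))
        w = plens * shares
        weights_within[ti] = w / w.sum()
        for j in range(config.proteins_per_taxon):
            pid = f"{taxon}_P{j + 1}"
            protein_ids.append(pid)
            protein_taxon.append(ti)
            lengths[pid] = int(plens[j])
            n_terms = int(rng.integers(1, 4))
            go_terms[pid] = frozenset(
                rng.choice(DEFAULT_GO_TERMS, size=n_terms, replace=False).tolist()
            )
            lineages[pid] = config.lineages[taxon]
    unique_peptides = 1 + rng.poisson(3.0, size=len(protein_ids))
    prob_high = rng.uniform(0.93, 1.0, size=len(protein_ids))
    prob_low = rng.uniform(0.5, 0.93, size=len(protein_ids))
    probabilities = np.where(rng.random(len(protein_ids)) < 0.85, prob_high, prob_low)

    # --- metagenome: one library per (treatment, day)
    mg_cols: dict[str, np.ndarray] = {}
    go_cols: dict[str, np.ndarray] = {}
    meta: list[SampleMeta] = []
    go_list = sorted(DEFAULT_GO_TERMS)
    for treatment in config.treatments:
        for day in config.days:
            p_read = _condition_vector(config, treatment, day, "metagenome")
            sid = f"mg_d{day}_{treatment}"
            mg_cols[sid] = _draw(rng, config.n_reads, p_read, config.overdispersion)
            # read-level GO weights follow the protein composition each taxon
            # expresses; a read contributes to exactly one term (MEGAN-style)
            go_w = np.zeros(len(go_list))
            for pi, pid in enumerate(protein_ids):
                ti = protein_taxon[pi]
                w = p_read[ti] * weights_within[ti][pi % config.proteins_per_taxon]
                for term in go_terms[pid]:
                    go_w[go_list.index(term)] += w
            go_cols[sid] = rng.multinomial(config.n_reads, go_w / go_w.sum())
            meta.append(
                SampleMeta(
                    sample_id=sid, day=day, treatment=treatment, tank="T1", layer="metagenome"
                )
            )

    # --- metaproteome: tanks x days x technical replicates
    run_counts: dict[str, np.ndarray] = {}
    for treatment in config.treatments:
        q = {day: _condition_vector(config, treatment, day, "metaproteome") for day in config.days}
        for tank in range(1, config.tanks_per_treatment + 1):
            for day in config.days:
                taxon_counts = _draw(rng, config.n_psm, q[day], config.overdispersion)
                prot_counts = np.zeros(len(protein_ids), dtype=np.int64)
                offset = 0
                for ti in range(n_taxa):
                    k = config.proteins_per_taxon
                    if taxon_counts[ti] > 0:
                        prot_counts[offset : offset + k] = rng.multinomial(
                            taxon_counts[ti], weights_within[ti]
                        )
                    offset += k
                split = rng.multinomial(
                    prot_counts, np.full(config.tech_replicates, 1.0 / config.tech_replicates)
                )
                group = f"mp_d{day}_{treatment}_tk{tank}"
                for rep in range(config.tech_replicates):
                    rid = f"{group}_r{rep + 1}"
                    run_counts[rid] = split[:, rep]
                    meta.append(
                        SampleMeta(
                            sample_id=rid,
                            day=day,
                            treatment=treatment,
                            tank=f"T{tank}",
                            layer="metaproteome",
                            tech_replicate_group=group,
                        )
                    )

    run_ids = list(run_counts)
    proteins = [
        ProteinRecord(
            protein_id=pid,
            length=lengths[pid],
            probability=float(round(probabilities[pi], 6)),
            unique_peptides=int(unique_peptides[pi]),
            spectral_counts={r: float(run_counts[r][pi]) for r in run_ids},
        )
        for pi, pid in enumerate(protein_ids)
    ]
    protein_table = CountTable(
        data=pd.DataFrame(
            {r: run_counts[r] for r in run_ids}, index=protein_ids, dtype=float
        ),
        layer="metaproteome",
        feature_kind="protein",
    )
    metagenome_taxa = CountTable(
        data=pd.DataFrame(mg_cols, index=list(config.taxa), dtype=float),
        layer="metagenome",
        feature_kind="taxon",
    )
    metagenome_go = CountTable(
        data=pd.DataFrame(go_cols, index=go_list, dtype=float),
        layer="metagenome",
        feature_kind="go_term",
    )
    annotations = AnnotationMap(lineages=lineages, go_terms=go_terms, lengths=lengths)

    conds = pd.MultiIndex.from_product(
        [config.treatments, config.days], names=["treatment", "day"]
    )
    p_frame = pd.DataFrame(
        {
            (tr, d): _condition_vector(config, tr, d, "metagenome")
            for tr, d in conds
        },
        index=list(config.taxa),
    )
    q_frame = pd.DataFrame(
        {
            (tr, d): _condition_vector(config, tr, d, "metaproteome")
            for tr, d in conds
        },
        index=list(config.taxa),
    )
    p_frame.columns = conds
    q_frame.columns = conds
    truth = SimulationTruth(
        p=p_frame,
        q=q_frame,
        activity=config.activity.copy(),
        psm_dropout=config.psm_dropout,
        read_dropout=config.read_dropout,
    )
    return SimulationResult(
        metagenome_taxa=metagenome_taxa,
        metagenome_go=metagenome_go,
        proteins=proteins,
        protein_table=protein_table,
        annotations=annotations,
        meta=meta,
        truth=truth,
        config=config,
    )


@dataclass
class RecoveryReport:
    """Estimated vs. true per-taxon activity bias, plus concordance and
    presence diagnostics for one simulated dataset."""

    per_taxon: pd.DataFrame
    concordance: list[ConcordanceResult]
    presence_confusion: pd.DataFrame


def recovery_report(
    truth: SimulationTruth,
    metagenome_taxa: CountTable,
    psm_taxon_table: CountTable,
    meta: Sequence[SampleMeta],
) -> RecoveryReport:
    """Compare pipeline estimates on simulated data with the generating truth.

    Estimated bias is log2 of the pooled PSM share over the pooled read share
    per taxon; truth is log2(q̄/p̄) from the generator's closed-form layer
    proportions.
    """
    taxa = list(truth.p.index)
    missing = set(taxa) - set(metagenome_taxa.features) | set(taxa) - set(
        psm_taxon_table.features
    )
    if missing - truth.psm_dropout - truth.read_dropout:
        raise ValidationError(f"taxa in truth but absent from estimates: {sorted(missing)}")
    reads = metagenome_taxa.data.reindex(taxa).fillna(0.0).sum(axis=1)
    psms = psm_taxon_table.data.reindex(taxa).fillna(0.0).sum(axis=1)
    read_ratio = reads / reads.sum()
    psm_ratio = psms / psms.sum()
    est = pd.Series(
        [activity_bias(read_ratio[t], psm_ratio[t]) for t in taxa], index=taxa
    )
    true = truth.pooled_log2_bias()
    per_taxon = pd.DataFrame(
        {
            "true_read_share": truth.p.mean(axis=1),
            "true_psm_share": truth.q.mean(axis=1),
            "true_log2_bias": true,
            "est_log2_bias": est,
            "abs_error": (est - true).abs(),
            "sign_match": np.sign(est).eq(np.sign(true)) | (true == 0),
        }
    )
    conc = concordance_by_condition(metagenome_taxa, psm_taxon_table, meta)
    presence = cross_layer_presence(metagenome_taxa, psm_taxon_table, meta)
    rows = {}
    for group, members in (
        ("psm_dropout", truth.psm_dropout),
        ("read_dropout", truth.read_dropout),
        ("other", set(taxa) - truth.psm_dropout - truth.read_dropout),
    ):
        sub = presence.loc[[t for t in taxa if t in members]]
        counts = pd.Series(sub.to_numpy().ravel()).value_counts()
        rows[group] = {
            s: int(counts.get(s, 0))
            for s in ("both", "metagenome_only", "metaproteome_only", "neither")
        }
    confusion = pd.DataFrame(rows).T
    return RecoveryReport(per_taxon=per_taxon, concordance=conc, presence_confusion=confusion)
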