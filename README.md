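# coupledomics

Coupled metagenome–metaproteome analysis of microbial communities: what a
community *could* do (DNA reads) versus what it *is* doing (peptide-spectral
matches, PSMs).

Sequencing detects which taxa and gene functions are present; mass
spectrometry detects which proteins are actually being expressed.  The two
layers routinely disagree — some taxa are far more metabolically active than
their genomic abundance predicts, others far less — and this package
quantifies that disagreement for time-series designs such as hatchery or
mesocosm water sampled across days and treatments.

## What it computes

For a feature *f* (taxon, GO term or protein) in library *s*, the
library-normalized relative abundance is `r_fs = c_fs / Σ_g c_gs`.  On top
of this the package provides:

- **Protein evidence filtering and NSAF.**  Proteins are kept when they have
  ≥ 2 unique peptides and a ProteinProphet-style probability ≥ 0.93
  (≈ 1% protein FDR); technical replicate injections are averaged on raw
  spectral counts; the normalized spectral abundance factor is
  `NSAF_i = (SpC_i / L_i) / Σ_j (SpC_j / L_j)` per sample, with `L_i` the
  protein length.
- **Temporal deltas.**  Per feature and treatment, first-zeroed differences
  `Δ_n = r_n − r_{n−1}` over consecutive observed days (`Δ_first = 0`), which
  telescope to `r_last − r_first`.
- **Concordance regression.**  For each (day, treatment), OLS of PSM ratios
  (y) on read ratios (x) with `R²`, measuring how well realized activity
  tracks genomic presence.
- **Activity bias.**  `log2((psm_ratio + ε) / (read_ratio + ε))` per taxon:
  positive = more active than presence predicts.
- **Cross-layer presence/absence.**  Each taxon × condition classified as
  both / metagenome_only / metaproteome_only / neither.
- **Diversity and community structure.**  Shannon–Weaver `H = −Σ p ln p`,
  Simpson reciprocal `1/D = 1/Σ p²`, Bray–Curtis dissimilarity, non-metric
  MDS (Kruskal stress-1) and the rank-based ANOSIM permutation test
  `R = (r̄_between − r̄_within) / (M/2)`, `M = n(n−1)/2`.
- **Differential GO terms.**  Laplace-smoothed log2 proportion ratios with a
  two-proportion z-test and Benjamini–Hochberg q-values (significant at
  q ≤ 0.05), plus per-taxon contribution breakdowns for each term.
- **A synthetic coupled-omics generator.**  Multinomial read and PSM counts
  from coupled proportion vectors `q_t = p_t a_t / Σ_u p_u a_u`, where `a_t`
  is a per-taxon activity multiplier; includes dropout taxa, triplicate
  technical runs and full ground truth for recovery testing.

## Worked example

```python
from coupledomics import (SimulationConfig, simulate, filter_proteins,
                          protein_count_table, average_technical_replicates,
                          compute_nsaf, aggregate_psms, bray_curtis, anosim,
                          recovery_report)

cfg = SimulationConfig.default(seed=42)      # 2 pH treatments x days 1,5,8,12
sim = simulate(cfg)

kept = filter_proteins(sim.proteins, min_unique=2, min_probability=0.93)
print(f"proteins retained: {len(kept)} / {len(sim.proteins)}")

averaged = average_technical_replicates(protein_count_table(kept), sim.meta)
nsaf = compute_nsaf(averaged, {r.protein_id: r.length for r in kept})

groups = {m.tech_replicate_group: m for m in sim.meta if m.layer == "metaproteome"}
days = [groups[s].day for s in nsaf.samples]
res = anosim(bray_curtis(nsaf), days, n_permutations=999, seed=42)
print(f"ANOSIM by day: R = {res.r_statistic:.4f}, p = {res.p_value:.3f}")

taxa = aggregate_psms(average_technical_replicates(sim.protein_table, sim.meta),
                      sim.annotations, level="taxon", rank="Class")
rep = recovery_report(sim.truth, sim.metagenome_taxa, taxa, sim.meta)
print(rep.per_taxon.loc[["Deltaproteobacteria", "Betaproteobacteria"],
                        ["true_log2_bias", "est_log2_bias"]].round(3))
```

prints

```
proteins retained: 100 / 125
ANOSIM by day: R = 0.9722, p = 0.001
                     true_log2_bias  est_log2_bias
Deltaproteobacteria           1.876          1.881
Betaproteobacteria           -2.083         -2.017
```

The evidence filter removes the proteins with weak support; proteome
composition separates cleanly by sampling day (ANOSIM p at its permutation
floor); and the estimated activity biases recover the generator's truth —
Deltaproteobacteria (multiplier 4) is strongly overactive relative to its
read abundance, Betaproteobacteria (multiplier 0.25) strongly underactive.

The same stages are exposed as a CLI
(`coupledomics simulate | quantify | concordance | community | godiff`), and
`coupledomics pipeline --out DIR --seed N` runs all of them on a simulated
dataset, writing every result as TSV.

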