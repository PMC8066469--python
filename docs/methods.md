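# Methods

## Scope and data model

The package analyzes paired views of one microbial community: metagenomic
read counts (potential function) and metaproteomic PSM counts (realized
function), both aggregated per feature (taxon, GO term, or protein) per
library.  It consumes *annotated* count tables and *scored* protein tables:
read trimming, gene prediction, database searching, protein inference and
LCA taxonomic annotation all happen upstream, and their outputs are the
package's inputs.  All files are strict TSV (UTF-8, `#` comments); missing
cells are errors rather than zeros, because a silently zero-filled cell is
indistinguishable from a genuine absence in the presence/absence analysis.

Taxonomic lineages run Kingdom → Phylum → Class and may be truncated.  When
a protein's lineage stops above the requested reporting rank it is counted
at its deepest available rank, so taxon tables mix ranks ("Bacteroidetes"
alongside "Flavobacteriia").  This mirrors LCA assignment, where many
proteins resolve only to coarse ranks, and it is why taxon feature ids are
exact strings with no fuzzy matching.

## Protein evidence and quantification

A protein enters the analysis when it has at least `min_unique = 2` unique
peptides pooled across all runs and a ProteinProphet-style probability of at
least `min_probability = 0.93` (the probability that corresponds to a 1%
protein-level FDR in an Abacus combined file; both thresholds are
configurable).  The unique-peptide requirement is interpreted as pooled
across runs, not per run.

Technical replicates (repeat injections of one biological sample) are
averaged **on raw spectral counts**, before any normalization.  Averaging
normalized values would weight low-yield runs more heavily; averaging raw
counts keeps each spectrum worth the same.  The operation is idempotent.

NSAF for protein *i* in sample *s* is `(SpC_is / L_i) / Σ_j (SpC_js / L_j)`
with `L_i` the length in amino acids; columns sum to 1 by construction and a
sample with no spectra at all is an error, not a zero column.

Aggregation to GO terms adds a protein's counts to **every** term it
carries.  Term totals therefore double-count spectra and must not be read
as spectrum totals; taxon aggregation, by contrast, conserves mass exactly
(each protein contributes to exactly one lineage bucket, with unannotated
proteins pooled under `unassigned`).

## Concordance statistics

Relative abundances are per-library ratios.  Temporal plots use first-zeroed
deltas `Δ_n = r_n − r_{n−1}` over consecutive *observed* days, with the
first observed day set to 0; a feature unobserved at a day gets ratio 0
(absence is informative in count data; carry-forward was rejected as an
invention).  The deltas telescope: `Σ Δ = r_last − r_first`, exactly.

Concordance is ordinary least squares of PSM ratios on read ratios — reads
are the predictor because the question is how well realized activity tracks
genomic presence — summarized by `R² = 1 − SS_res/SS_tot`.  By default
per-day ratios are regressed; a flag regresses per-interval deltas instead,
in which case each treatment's first observed day is skipped (its deltas are
identically zero and the fit is degenerate).  When the response is constant,
`R²` is reported as 0 (no explained variance).  Features missing from one
layer are zero-filled before regression.

Activity bias for a taxon is `log2((psm_ratio + ε)/(read_ratio + ε))` with
`ε = 1e-6` (small against any observable ratio, only there to keep zeros
finite); exactly equal ratios return exactly 0.  Under the generator's
model the estimator is consistent for `log2(q_t/p_t)`.

## Community analyses

Shannon–Weaver uses natural log (configurable base); Simpson reciprocal is
`1/Σ p²`.  Both work on proportions, so they are invariant to library size —
which is also why any per-library "normalized reads" rescaling upstream has
no effect on them.

ANOSIM ranks all `M = n(n−1)/2` pairwise Bray–Curtis dissimilarities (ties
averaged) and computes `R = (r̄_between − r̄_within)/(M/2)`.  The null
distribution permutes group labels; `p = (1 + #{R_perm ≥ R_obs})/(1 + n_perm)`,
so 999 permutations have a p floor of 0.001 — the reporting convention of
vegan.  For small n an exhaustive mode enumerates every distinct label
permutation and returns the exact p, which doubles as the test oracle for
the sampler.

NMDS minimizes Kruskal stress-1 by SMACOF with isotonic (monotone)
regression, 20 seed-derived random restarts, best stress kept.  The
embedding is centered, rotated to principal axes, and sign-fixed
(largest-magnitude loading per axis made positive) so one seed always yields
one orientation.  Non-convergence sets a flag instead of raising.  The
metaproteome ordination runs on NSAF profiles by default; taxon tables work
too.

## GO differential testing

The exact behavior of web-service differential tools is not reproducible,
so the module fixes a transparent statistic: with pooled term count `k` and
library total `N` per condition, the smoothed proportions
`(k + pseudo)/(N + pseudo)` (Laplace `pseudo = 1`) give a log2 ratio and a
two-proportion z-test with pooled variance; swapping conditions negates the
ratio and preserves p.  Benjamini–Hochberg q-values are computed within each
comparison and a term is significant at `q ≤ α = 0.05`.  Comparisons cover
consecutive-day pairs within each treatment and treatment pairs within each
day.  Only prokaryote-annotated proteins (Kingdom Bacteria or Archaea)
enter by default, since eukaryotic host and feed peptides confound water
community profiles.  Library totals are protein-level PSM totals, not sums
over GO terms (which double-count).  GO-DAG propagation to ancestor terms is
deliberately not performed.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the study's design shape: 2 treatments (pH 7.1 / 8.2) × 4 days (1, 5, 8,
12), 25 mixed Kingdom–Class taxa, 2 proteomics tanks per treatment with
triplicate injections, one metagenome library per condition.

- **Coupling.**  Reads ~ Multinomial(n_reads, p); PSMs ~ Multinomial(n_psm,
  q) with `q ∝ p · a` for activity multipliers `a`.  Default multipliers
  encode the over/under-active pattern coupled datasets show
  (Deltaproteobacteria 4, Alphaproteobacteria 2; Betaproteobacteria 0.25,
  Cytophagia/Gammaproteobacteria/Flavobacteriia 0.5; others 1).
- **Trajectories.**  Baseline log-normal taxon weights with a few dominant
  taxa boosted; day-to-day change is a multiplicative random walk
  (σ = 0.4) **shared between treatments** — both treatments draw the same
  source water, so temporal shifts dominate — plus an independent
  treatment jitter (σ = 0.15) per condition.  This reproduces the
  study-style ANOSIM outcome: strong day structure, negligible pH
  structure.
- **Proteins.**  5 per taxon; lengths uniform on 100–1000 aa; expression
  shares Dirichlet(1); PSMs land on proteins ∝ length × share and split
  uniformly-multinomially across 3 technical replicates.  Probabilities and
  unique-peptide counts are simulated (85% above the 0.93 threshold;
  `1 + Poisson(3)` unique peptides) so the evidence filter has a nontrivial
  surface.
- **Dropout.**  Default PSM-layer dropout: Archaea and candidate division
  NC10 — taxa present genomically but never detected proteomically,
  exercising the presence/absence classifier.
- **Library sizes.**  Defaults are 10⁶ reads per metagenome library (a
  desk-scale stand-in for production HiSeq libraries; the package's choice
  of problem size) and 3×10⁴ PSMs per proteomics sample (a realistic
  single-sample Orbitrap yield over triplicate injections).  Recovery tests
  use 10⁶ PSMs to isolate estimator behavior from counting noise.

What the generator deliberately does **not** model: overdispersion beyond
multinomial (a Dirichlet-multinomial option exists, default off so oracles
stay closed-form), biological tank-to-tank variation (tanks within a
condition differ only by counting noise, which is why simulated day-ANOSIM
R approaches 1 rather than the intermediate values real data show),
peptide-level detectability bias, chimeric annotations, or any dynamic
model of blooms beyond piecewise-constant jumps.  Passing recovery tests
therefore demonstrates estimator correctness under the model's assumptions,
not robustness to real-data violations of them.

## Numerical conventions

- Floats in TSV output carry 6 significant digits; raw counts are exact.
- NSAF and ratio columns sum to 1 within 1e-9; telescoping holds to 1e-12.
- Mass conservation of taxon aggregation is bit-exact on raw integer
  counts; replicate averaging introduces thirds, so the averaged-path check
  allows float-associativity noise (rtol 1e-12).
- All stochastic components (simulation, ANOSIM permutations, NMDS
  restarts) are driven by explicit integer seeds; identical seeds give
  byte-identical pipeline output.
- ANOSIM permutation comparisons use a 1e-12 slack when counting
  `R_perm ≥ R_obs` so rank ties do not flip on float noise.

## Known limitations

- The probability threshold stands in for full FDR machinery; no attempt is
  made to re-estimate FDR from decoys.
- GO multi-assignment means term-level totals are not spectrum totals;
  fractional splitting is not offered.
- The z-test on smoothed proportions is a transparent approximation; exact
  binomial alternatives would be preferable at very small totals.
- NMDS stress comparisons across dimensions are only meaningful at the
  global optimum; with few samples and near-degenerate geometry restarts
  can land within optimizer noise of each other.
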