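# Methods

## Model

`pathcause` treats pathway extraction as a consistency check between curated
mechanism fragments and observed molecular variation. A *causal prior* is a
directed, signed, optionally site-annotated relation between two gene
symbols, of one of four types: phosphorylation, dephosphorylation,
expression upregulation, expression downregulation. A *causal conjecture*
pairs one prior with a source feature and a target feature from the data
such that a ternary parity equation holds.

All signs live in the three-valued domain {true, false, unknown} closed
under negation and XOR, with the convention that any `unknown` operand
makes an expression `unknown` — an undetermined term can never support a
causal claim. The two governing equations are

    comparison :   c_src ⊕ e_src ⊕ s_rel ⊕ ¬c_tgt = true
    correlation:   corr(src, tgt) ⊕ e_src ⊕ s_rel = true

with `c` a feature's change direction, `corr` the sign of a significant
pairwise correlation, `e` the effect of the source feature on its protein's
activity (total protein and injected activity read true; phosphosites read
their curated effect, defaulting to unknown), and `s` the relation sign
(true for phosphorylation / expression upregulation). Because ternary XOR
over determined values is parity, the comparison equation accepts exactly 8
of the 16 fully-determined four-term assignments and the correlation
equation exactly 4 of 8 — an enumeration the test suite verifies against an
independent brute-force oracle.

Structural applicability precedes the sign logic: phospho relations explain
only phosphosite features whose measured site matches a prior-annotated
site; expression relations explain only total-protein (optionally RNA)
features; sources must carry protein-level evidence (total protein,
phosphosite, or an activity hypothesis), never RNA; hypothesis rows act
only as sources; a row never explains itself. A relation is reported once,
with all supporting conjectures retained. Relations whose evidence carries
opposite signs through different feature pairs are all reported; none is
suppressed, since the method makes no claim of exclusivity.

## Statistical assessments

**Changes (comparison mode).** Per-row two-sample tests on complete cases
per group, Welch by default (proteomic groups are routinely
heteroscedastic; a pooled-variance option exists), two-tailed, unpaired.
Rows with fewer than `min_group_n` (default 3) usable values in either
group are untestable. P-values are pooled for Benjamini–Hochberg adjustment
*per feature kind* (phospho, total protein, RNA) because the kinds differ
systematically in variance structure and missingness; a row's direction is
its change sign if its q-value passes `feature_fdr` (default 0.1), else
unknown. A mean-difference ("fold change") caller with a symmetric dead
band is available when group sizes cannot support a test. Activity
hypotheses carry their stated direction and are exempt from FDR.

**Correlations (cohort mode).** Pearson by default (Spearman selectable),
pairwise-complete, untestable below `min_corr_n` (default 5) shared samples
or under zero variance. BH is applied over exactly the distinct feature
pairs linked by at least one applicable prior — not all pairs — so the
multiple-testing family is the set of candidate explanations the engine
actually examines. A pair's correlation sign enters the parity equation
only when its q-value passes `correlation_fdr` (default 0.1). With
`fdr_control` off, both thresholds apply to raw p-values instead.

**Site matching.** At tolerance 0 a prior site must match a measured site
exactly (residue and position). Literature site coordinates are often
shifted by one or two positions relative to canonical UniProt numbering
(initial-methionine cleavage being the classic cause), so a configurable
tolerance (±2 is the conventional choice) matches by position only; a
strict-residue flag restores residue agreement under tolerance. Priors
without site annotation may match any measured site on the target
(`unsited_prior_matches_any`, default on, reflecting heterogeneous site
resolution across curation sources); this is configurable off.

**Multi-site and multi-symbol rows.** A phosphopeptide spanning several
annotated sites takes the unanimous curated effect or unknown (conservative:
disagreeing annotations veto). Rows mapping to several gene symbols are
considered under each symbol independently when matching priors.

## Permutation significance

Both tests randomize the assignment of molecular identities (symbols +
sites + effect annotation) to value vectors, uniformly among rows of the
same feature kind, leaving the vectors — hence the data's change and
correlation structure — untouched while severing its link to the prior
network. Shuffling sample labels instead would alter the number of
significant features and conflate two different nulls; the chosen unit
isolates "do the priors align with the data" as the question. Hypothesis
rows are never shuffled. The module API admits alternative schemes.

The network-size test compares the observed count of accepted relations
with its permutation distribution; the downstream-size test does the same
per source protein for the count of distinct explained targets, with BH
across the tested proteins (those sourcing at least one accepted relation;
default report threshold 0.1 FDR). Monte Carlo p-values use the add-one
estimator (r+1)/(n+1), never zero and conservative under ties. Defaults are
10,000 permutations for the single network-size p-value and 1,000 for the
downstream family. An exhaustive mode enumerates every label bijection
(product of per-kind factorials, bounded at 5×10^5) and reports the exact
fraction with statistic ≥ observed, identity included; it exists so small
cases can be checked against direct enumeration.

Internally the permutation loop uses a lookup fast path: change assessments
and pairwise correlations depend only on the value vectors, so they are
computed once and permutations merely re-resolve which row holds which
identity. The test suite checks that this path reproduces the full engine
on explicitly permuted datasets in both modes.

## Synthetic data

The generators emulate the statistical structure the analyses assume, not
mass-spectrometry artifacts. Defaults (the package's reference study
conditions): 50 proteins, edge density 0.05 over ordered pairs (~122
relations) mixed 62/7/23/8% across the four types — echoing the
literature's representation bias toward phosphorylation — with phospho
relations carrying 1–3 target sites. Each protein owns one regulatory
"activity" phosphosite; 80% are annotated (70% of those activating). A
planted-active set (30% of discoverable relations, i.e. those with an
annotated source effect) receives signal constructed *before* data so
equation-consistency is constructive rather than rejection-sampled:

* comparison datasets shift the source feature by ±3σ between groups
  (10 samples per group) and give the target the direction that solves the
  parity equation (`c_tgt = c_src ⊕ e ⊕ s`);
* cohort datasets (100 samples) give source and target loadings √ρ on a
  shared standard-normal latent factor (ρ = 0.8), signed so
  `corr = ¬(e ⊕ s)`; ρ = 0 yields an exact global null.

Noise is independent Gaussian per feature; 10% of cells go missing
completely at random. Ground truth (the planted relation keys) accompanies
every dataset, and precision/recall against it is the module's contract.
What passing these tests does *not* show: robustness to peptide-level
artifacts (shared peptides, ionization effects), correlated noise across
features, batch structure, or informative missingness — real proteomic
data have all four.

## Calibration and problem sizes

The null-calibration check runs 200 independent ρ = 0 cohorts at the
reference conditions and tests the network-size p-values for uniformity
(Kolmogorov–Smirnov at α = 0.01) and the empirical type-I error at
α = 0.05 (accepted band 0.05 ± 0.02), using 999 permutations per cohort
for a fine p-grid. Feature selection in this check uses the uncorrected
per-pair threshold rather than BH: under a global null, BH produces a
network-size statistic almost always zero, pinning the permutation p at 1
and making a uniformity test meaningless, whereas the permutation test's
validity is agnostic to the selection rule. Planted-recovery checks use
the reference conditions above with 1,000 permutations for the network-size
test; the exact downstream check uses a 4-row star where all 24 label
bijections are enumerable.

## Numerical and design notes

* Gene symbols are uppercased on load and compared case-sensitively after.
* Exact duplicate priors (same source, type, target, sites) collapse on
  load with mediator provenance merged; the same pair annotated at
  different sites is kept as distinct site-resolved variants.
* Self-edges (autophosphorylation) are retained and flagged.
* Neighborhood restriction keeps relations reachable within `hops`
  undirected steps of a seed set (multi-source BFS); it is idempotent and
  monotone in `hops`.
* Zero-variance t-test inputs: equal group means are untestable, unequal
  means with identical within-group values report an infinite statistic at
  p = 0 rather than failing.
* BH adjustment passes missing p-values through as missing without
  counting them toward the number of tests.
* Precision estimators report half-up rounding to two decimals (29/32 →
  0.91) with raw ratios retained; the noise-adjusted count is clamped at
  zero if contrary cases ever exceeded expected-direction cases.
* The result JSON schema is artifact-specific and versioned
  (`schema_version: 1`).
* Paired designs and one-tailed tests are not implemented; inputs must
  arrive normalized (no imputation, batch correction, or peptide-to-protein
  rollup is performed).
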