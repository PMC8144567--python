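# Methods

This note documents the models, parameter choices and numerical decisions
behind `npcpgx`, and what the synthetic generators do and do not emulate.

## Dose–response model and IC50 censoring

Viability is expressed as percent of control wells:
`100 · raw / mean(controls)`, with negative raw luminescence clipped to 0
before division; a non-positive control mean is rejected as a dead plate.
Potency is the IC50 of a four-parameter log-logistic (Hill) curve

    v(d) = bottom + (top − bottom) / (1 + (d / IC50)^h)

fitted by bounded least squares on log-dose (`scipy.optimize.least_squares`)
with bottom ≥ 0, top ≤ 120% and h > 0. Replicates are averaged per dose
before fitting, matching how screen response curves are usually reported
(mean % viability ± SEM). Initialization takes top/bottom from the data
extremes, IC50 from the geometric mean of the doses, h = 1, with up to three
jittered restarts on optimizer failure. A fitted span of < 5 percentage
points (no dose effect) or an inverted (rising) curve is flagged
non-converged: such arms carry no usable IC50.

The tested range is 0.08–20 µM (six 3-fold dilutions). Fitted IC50s outside
it are not extrapolated: values above 20 µM are reported at the 20 µM
ceiling (`clipped_high`), below 0.08 µM at the floor (`clipped_low`), and
non-converged fits at the resistant ceiling (`nonconverged`). The censoring
status is carried in all outputs so the proxies are never mistaken for
in-range estimates. Censoring guarantees strictly positive IC50s on both
sides of a fold-change ratio.

## Bliss synergy calling

Inhibition fractions are `1 − v/100`, clipped to [0, 1]. The additive
reference for a drug–radiation pair is the Bliss-independence surface
evaluated per dose, `E_total(d) = E1 + E2(d) − E1·E2(d)`, with E1 the
ionizing-radiation inhibition at the screen dose (4 Gy by default,
configurable). A pair is **synergistic** when the observed combination curve
exceeds the additive inhibition by more than `tol` (default 0.02, i.e. 2
viability percentage points) at ≥ `min_points` doses (default 3 of 6);
**additive** when within ±tol everywhere; otherwise
**antagonistic-or-none**. The defaults are reported in every output because
"lower than the additive curve" has no canonical numeric reading.

By default the comparison uses the fitted 4PL curves evaluated on the dose
grid rather than raw replicate means (`smooth=True`): at realistic assay
noise (SD ≈ 3% viability, 3 replicates) the per-dose scatter of raw means
is comparable to the 2 pp tolerance, and smoothing through the fitted curve
keeps the false synergy-call rate at offset 0 near 3% while detecting a
0.15 inhibition offset essentially always (measured over 200 simulations
per condition in the acceptance suite). The raw-mean comparison remains
available (`smooth=False`). Non-converged arms fall back to raw means.

The fold change is `IC50_mono / IC50_combo` on proxy-censored values, and
"good combination" means strictly > 3; the boundary 3.0 is not flagged.

## Variant consensus and filters

Callers are merged on the key (chrom, pos, ref, alt); a variant is consensus
when ≥ 2 callers (configurable) report it. The surviving annotation record
comes from the caller with the greatest tumor depth, ties broken by caller
name, so merges are deterministic. Filters are a conjunction of strict
comparisons — population allele frequency < 4e-4, tumor depth > 20, tumor
alt reads > 3, matched-normal alt reads < 1, tumor VAF > 0.05 — hence
idempotent and order-independent; each rejected variant carries the first
failing criterion as a reason code. The normal-reads criterion admits a
literal alternative reading ("reference-supporting reads < 1") kept behind
`FilterConfig.normal_clause="literal_ref_reads"`; it is not the default
because it would discard essentially every genuine call (a passing variant
with depth 25 and 4 alt reads has 21 reference reads). An optional
low-mappability mask uses 0-based half-open BED intervals converted to the
1-based variant coordinate (interval [s, e) masks 1-based positions
s+1 … e).

Burden reporting uses half-up rounding (2662 variants over 88 samples →
30.3/sample); Python's default banker's rounding would print 30.2.

SNVs are binned into the 96 pyrimidine-centered trinucleotide classes
(substitution-major order, purine-centered calls reverse-complemented).
Catalog refitting is nonnegative least squares (`scipy.optimize.nnls`) of
the catalog frequency vector onto reference-signature columns, weights
rescaled to exposures summing to 1, with the reconstruction cosine reported.
An exome-to-genome re-weighting multiplies each context frequency by a
supplied genome/exome trinucleotide ratio before fitting. The bundled
reference (`data/reference_signatures_synthetic.tsv`) is a **synthetic**
96×5 matrix shaped like familiar processes (clock-like NpCpG C>T, APOBEC-like
TpC, tobacco-like C>A, mismatch-repair-like, flat); it is generated
deterministically by `variants.synthetic_reference_signatures()` and is not
any published catalog.

## Differential expression and the overlap filter

Counts are normalized with median-of-ratios size factors (computed over
genes nonzero in all samples; total-count fallback with a warning) and
log2(x/sf + 1). Two deliberately different tests share one effect estimate
(mean difference of normalized log2 values, oriented by sorted group-label
order so relabeling flips the sign): method A is a moderated t-test whose
pooled per-gene variance is shrunk toward the gene-wise median with 4 prior
degrees of freedom; method B is the two-sided Wilcoxon rank-sum test. These
are stand-ins for running two independent DE engines — the scientific
content exercised here is the *overlap rule*: a signature gene must clear
|log2FC| > 1, p < 0.05 and BH-adjusted p < 0.05 in **both** methods.
BH adjustment uses `statsmodels` (`fdr_bh`). Signature lists are
intersected with pathway gene sets (GMT) and the union over pathways forms
the combined signature used for scoring.

## ssGSEA, labeling and ROC

Per sample, genes are ranked by expression (midranks for ties); walking the
ranking from highest to lowest, the enrichment score is the summed
difference between the in-set ECDF weighted by rank^α (α = 0.25, the common
literature default; the score is otherwise unparameterized here) and the
uniform out-of-set ECDF. Only ranks enter, so any strictly increasing
transform of expression leaves scores unchanged — asserted as a property
test. Raw scores feed the ROC (AUC is invariant to the min-max rescaled
presentation variant, which is also available).

Samples are labeled from the IC50 phenotype: the floor(q·n) lowest IC50s are
sensitive, floor(q·n) highest resistant (q = 0.10), the rest unlabeled;
boundary ties break by stable input order for determinism. AUC is the
midrank Mann–Whitney statistic with the sensitive class positive (the
orientation is recorded in the result), equal to the tie-corrected pairwise
concordance probability — verified exhaustively against brute-force
enumeration for all labelings up to n = 8 and against scikit-learn.
Score–response association is point-biserial Pearson (sensitive = 1);
constant scores yield a missing value with a reason, never a silent zero.
The random-signature null draws gene sets uniformly without replacement,
scores and evaluates each identically, and summarizes the AUC distribution;
with labels independent of expression its mean sits at 0.5.

## Synthetic generators: what they emulate, and what not

- **Cohort**: subtype labels at the study composition (57/106 EC, 26/106
  MSEC, 20/106 SC, 3/106 SCC) by largest-remainder rounding (counts sum
  exactly to n; ties by input order), organoid availability at the observed
  40/43 establishment rate.
- **Plates**: four-parameter log-logistic truth plus additive Gaussian
  noise on the % scale truncated at 0 (SD 5% default, 3 replicates — the
  replicate count screens typically report). Combination arms place the
  expected inhibition at Bliss-additivity plus a synergy offset, clipped to
  [0, 1], so offset 0 is exactly additive by construction.
- **Call sets**: true variants are emitted by ≥ 2 of 3 callers (all three
  with probability 0.7) with deep, clean, database-absent annotations;
  false positives are caller-private with shallow/noisy annotations. This
  makes consensus precision exactly 1 by construction — a known-truth
  regime for testing the merge rule, not a model of real caller error
  correlation.
- **Expression**: negative-binomial counts, gene-wise dispersion
  log-uniform (0.05–0.5 default), log-normal baseline means, an exact
  2-fold library-size spread, and a signature-gene block shifted by a
  chosen log2FC in one group. The IC50 phenotype is log-linear in
  standardized true signature activity with Gaussian noise, clipped to the
  tested range.

Not emulated: sequencing reads, caller error correlation, copy-number
structure, batch effects, within-subtype heterogeneity, or real pathway
co-expression. Passing tests therefore demonstrate the correctness and
calibration of the *computations* under their stated assumptions, not
performance on real cohorts.

## Problem sizes and determinism

All randomness flows from `numpy.random.default_rng` seeds; one global seed
fans out to per-stage child seeds by CRC32 hashing of the stage name, so
stages rerun in isolation reproduce the full-pipeline inputs, and demo
reports are bit-identical under a fixed seed. Simulation-based checks use
200 plates (IC50 recovery), 200 simulations per condition (synergy operating
characteristics), 2000 null genes (test calibration), and a 2000-gene ×
200-sample cohort with 200 random 105-gene signatures (null-AUC
calibration) — sizes at which the Monte-Carlo error of each checked
quantity is comfortably below its assertion tolerance.

## Known limitations

- The 4PL fit reports a single IC50 without confidence intervals; censored
  estimates are point proxies, so downstream fold changes saturate at the
  range ratio (250).
- The moderated test's prior df is fixed (4) rather than estimated
  empirical-Bayes style; it is a stand-in, not a DESeq2/limma replica.
- ssGSEA normalization across gene sets of different sizes is not applied;
  scores are comparable across samples within a set, not across sets.
- The synthetic reference-signature matrix is well-conditioned; real
  refitting problems with many correlated signatures are harder than this
  test bed.
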