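# Methods

`bloodtrac` re-implements, as a tested library, a whole-blood RNA-seq
biomarker workflow for coronary artery disease (CAD): RPKM normalization,
a multi-stage differential-expression filter cascade that selects
transcripts associated with CAD (TRACs), a composite transcript score
with diagnostic evaluation, cell-type and gene-set enrichment, and the
arithmetic that links regulatory-T-cell (Treg) abundance to marker-RNA
fold changes. Because the workflow is exercised end to end on synthetic
data, the cell-mixture cohort generator is itself first-class, tested
code, and this note describes both the analysis model and what the
generator does and does not emulate.

## The analysis model

**Normalization.** Raw per-transcript read counts are converted to RPKM,

    RPKM_ts = count_ts / ((length_t / 1000) · (total_s / 10^6)),

with `total_s` the sample's mapped informative reads (defaulting to the
matrix column sum). No further between-sample normalization is applied —
downstream group comparisons operate on raw RPKM or log2(RPKM + offset).
A conservation identity, Σ_t RPKM_t·kb_t = 10^6 per sample when totals
are column sums, is enforced by test.

**Group structure.** Samples carry an angiographic stenosis group:
LOW (≤ 20%), MID (> 20% and < 70%), HIGH (≥ 70%); both boundary values
are inclusive toward LOW and HIGH respectively. Two-group analyses pool
MID and HIGH into MID+ and compare against LOW.

**The TRAC cascade.** Four nested stages over an RPKM matrix:

1. *expression filter* — keep transcripts with RPKM > 0.01 in ≥ 70% of
   the samples of at least one group;
2. *group test* — per-transcript Welch two-sample t-test on
   log2(RPKM + c), uncorrected p < 0.001 defines the DEG list (for two
   groups the Welch one-way ANOVA F equals t², verified to 1e-9);
3. *volcano selection* — p < 0.001 and |signed fold| > 1.5;
4. *parent list* — DEGs above the 20th percentile of expression in both
   groups, then those with > 1.4-fold decrease in MID+.

Fold changes are ratios of group geometric means, signed so that a
decrease in the disease group prints as the negative reciprocal (−1.57
means 1.57-fold down). Benjamini–Hochberg q-values are reported alongside
but never filtered on, matching the uncorrected-p design. Percentile
ranks use the fraction-strictly-below convention,
rank = 100·#{below}/(n−1), ties sharing a rank.

**Covariate biomarker lists.** The same volcano machinery at > 3-fold and
p < 0.05 builds per-covariate transcript lists (sex, age ≥ 60, BMI,
smoking, hypertension, diabetes, dyslipidemia, aspirin, read depth).
Demographic covariates (age, sex, BMI) are analyzed within LOW-CAD
samples only so the CAD contrast cannot confound them; list overlaps with
the TRAC set are reported as counts.

**Composite score and evaluation.** For a panel of k transcripts, each
transcript is expressed as the ratio to its mean across the whole cohort
and the k ratios are averaged per sample, preventing highly expressed
transcripts from dominating; the cohort mean of each ratio is 1 by
construction. TRAC panels are oriented lower-is-disease, and orientation
is explicit everywhere a score meets labels. Discrimination is summarized
by the empirical C-statistic (Mann–Whitney AUC with ties at ½) — not a
fitted binormal ROC model, so values can differ slightly from
binormal-model software on the same data. Confusion matrices are taken at
an explicit score threshold (cohort median by default, since no published
threshold exists to copy), and printed PPV/NPV pairs can be inverted into
integer count matrices via `confusion_from_predictive_values` for
reconstruction checks. Welch tests from printed mean/SEM/n summaries
(`summary_ttest`) reproduce demographic-table p-values.

**PLS-DA.** Partial least squares discriminant analysis uses NIPALS
(scikit-learn's `PLSRegression`) on standardized predictors with a ±1
class code; class is the sign of the fitted response. Validation is
stratified N-fold (default 5), seeded. Predictions are invariant to
duplicating predictor columns, which is enforced by test.

**Clinical risk points.** The additive comparator model sums integer
points per clinical factor level and maps the total through ordinal
cutpoints. No published point table ships with the package — the table is
a user-supplied YAML config, and the repository includes an explicitly
toy table for tests and demos only.

**Enrichment.** Overlap of two symbol sets A, B in a universe of N
symbols reports fold over-representation k·N/(|A||B|) and the upper-tail
hypergeometric p = P(X ≥ k) (one-sided Fisher exact; a two-sided variant
doubles the smaller tail). N is an explicit required parameter: published
enrichment folds and p-values are reproducible only conditional on a
universe, so none are hard-coded. Cross-cohort matching is at the gene
symbol level, upper-cased; when transcripts collapse to symbols the
highest-mean-expression transcript represents the symbol. "Close" symbol
matches use a frozen two-rule definition — identical after dropping one
trailing alphanumeric character (ELP3 vs ELP2), or Levenshtein distance 1
with identical leading alphabetic stem — and every reported pair carries
the rule that fired so alternative definitions can be compared.

**Treg arithmetic.** A fractional reduction r in a cell compartment
translates to a 1/(1−r) fold in RNA exclusive to it; compartment
fractions f₁, f₂ imply fold f₁/f₂. The two forms are algebraically
identical (tested over a grid): a 30.3% Treg reduction gives 1.43-fold,
and 4.7% vs 3.2% of lymphocytes gives ≈ 1.47-fold.

## The synthetic cohort generator

Whole-blood expression is a convex mixture over six cell types
(granulocyte, monocyte, B, NK, conventional T, Treg): sample s with RNA
contribution fractions f_{s,c} has expected relative abundance
Σ_c f_{s,c}·rate_{c,t} for transcript t. Two independent disease signals
are planted:

* **Treg depletion** — Tregs contribute 4.7% of lymphocyte RNA in LOW,
  3.2% in MID+ (2.8% in HIGH when present), with the lymphocyte total
  held constant and conventional T cells absorbing the difference; a
  Treg-exclusive marker therefore falls by exactly 4.7/3.2 ≈ 1.47 in
  expectation, with no per-cell expression change anywhere.
* **TRAC program** — 50 designated transcripts have their rates divided
  by 1.7 in every cell type of MID+/HIGH samples. TRACs are expressed
  uniformly across cell types so the planted fold is exactly 1.7,
  untouched by fraction shifts, and are drawn from the 55th–95th
  expression percentile so a 1.7-fold effect is observable over counting
  noise at n = 48 per group (as the real effect evidently was).

Noise model and defaults, chosen once:

| knob | default | rationale |
|---|---|---|
| transcripts | 2,000 | desk scale; every contract is exercised without the full 157,943-transcript universe |
| samples | 48 LOW / 48 MID | the discovery-cohort design |
| library size | 2×10^5 reads, CV 30% | desk scale of "millions of informative reads varying ~30%" |
| baseline rates | log-normal, σ chosen so ~2,000 draws span ~23 log2 units | the observed dynamic range, with one hemoglobin-like transcript pinned near RPKM 65,000 |
| fractions | Dirichlet, concentration 150 | granulocyte CV ≈ 15%, lymphocyte ≈ 10%, Treg ≈ 46% — the range of reported between-person leukocyte variability |
| counts | negative binomial (gamma–Poisson), size 10 | ≈ 32% patient-level CV beyond Poisson, matching visibly super-Poisson real data |
| transcript lengths | uniform 500–10,000 bp | RPKM ≠ counts, so length correction is genuinely exercised |
| markers | 12 exclusive markers per cell type, 60th–90th percentile | composite cell-type indices of 10–15 well-measured transcripts |

One integer seed drives named substreams (profiles, fractions, library,
counts, covariates), so each stage is independently reproducible and a
fixed config + seed yields bit-identical pipeline outputs (SHA-256
digests recorded in the run manifest).

Simulated clinical covariates follow the discovery-cohort marginals (age
57.5 vs 62.5, 45.8% vs 56.2% male, etc.) but are drawn independently of
expression: covariate biomarker lists on simulated data behave as nulls.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: isoform structure and alignment ambiguity,
reference-genome effects, batch and RNA-stabilizer effects, correlated
regulatory programs beyond the single planted TRAC multiplier,
covariate–expression coupling, rRNA contamination and sequencing-error
structure. Recovery results certify the machinery, not clinical
performance; on this clean mixture model the composite panel separates
groups more sharply (C ≈ 0.98 at desk scale) than any real cohort would.

## Numerical choices

* **Log offsets.** Geometric means and folds use x + 1e-6 (configurable);
  a geometric mean is reported offset-subtracted, floored at 0, while
  folds are taken on the offset scale so they stay finite. The Welch test
  uses a *different* pseudo-count, the 0.01-RPKM detection floor: with an
  offset of 1e-6 a single zero count maps to log2 ≈ −19.9 and one such
  outlier inflates the group variance enough to mask genuine 1.7-fold
  effects in low-count transcripts.
* **Percentile convention** (fraction strictly below, ties share, n = 1
  → 0) is frozen; no convention is canonical.
* **Degenerate tests.** Zero-variance transcripts with equal group means
  get t = 0, p = 1; unequal means give p = 0 with signed infinite t.
* **Confusion inversion** rounds ppv·n to the nearest integer; metrics
  recompose to the inputs within the 1/n rounding granularity.
* **Welch over pooled t** everywhere (including `summary_ttest`), frozen
  after verifying that printed demographic p-values reproduce under it.
  A small number of published summary rows (e.g. red-cell indices) do not
  reproduce under any standard two-sample test from their printed
  summaries; they are not special-cased.
* **Fold-type choice.** Fold changes are ratios of geometric means
  (group summaries are explicitly geometric); an arithmetic variant is
  not offered.

## Verification design

Oracles are independent of the paths they check: the C-statistic is
compared against brute-force pair counting (exact, with ties, up to
n = 200), hypergeometric p against full enumeration of draws (N ≤ 15),
hand-computed t and correlation values against closed forms, and the
mixture arithmetic against the generator's analytic truth table.
Cohort-level checks run at fixed seeds: planted-TRAC recovery ≥ 80% with
≥ 95% down-direction concordance at the default 48/48 design; type-I
error within binomial 3σ on a null cohort (no planted effects); and the
Treg marker fold within 5% of 4.7/3.2, measured on the depth-normalized
marker index at 2,000 samples per group so the 5% band sits near 3σ of
the estimator given the ~46% between-person Treg variability.

## Known limitations

* The empirical AUC is not a binormal-model AUC; comparisons against
  binormal-fitted C-statistics carry a small systematic difference.
* Enrichment results depend entirely on the user-supplied universe size.
* The cascade tests transcripts independently (no variance shrinkage or
  moderated statistics), by design fidelity rather than statistical
  preference.
* The simulator's compositional model means any large planted effect
  perturbs all other transcripts slightly (closure); at the planted
  effect sizes used this perturbation is ≪ 1% and ignored.
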