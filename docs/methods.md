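# Methods

## The analysis

The package operationalises a ratio-based cytokine biomarker workflow for
two binary questions about ICU patients: does the patient have a bloodstream
infection (BSI yes/no), and, among confirmed BSIs, is the organism
Gram-negative or Gram-positive. The stages, in execution order:

1. **Cohort table.** Tidy per-sample CSV: 21 cytokine concentrations
   (pg/mL, complete by assay design), outcome labels (`bsi`, `gram`, with
   `gram = n/a` exactly when `bsi = no`), demographics and four traditional
   lab markers (CRP, PCT, lymphocytes, NE%) that may be missing.
2. **Ratio features.** All sums of 1–3 distinct pro-inflammatory cytokines
   over sums of 1–3 distinct anti-inflammatory ones. The panel assigns 14
   analytes to the numerator pool and 6 to the denominator pool; MIP-3α is
   deliberately unassigned (its inflammatory role is debated) and appears
   only as a raw feature. Counts: 469 numerator × 41 denominator subsets =
   19,229 ratios; 19,250 features with the raw panel. Members are sets, not
   multisets, and enumeration order is lexicographic in (numerator,
   denominator) subset indices so feature positions are reproducible.
   Ratio values are invariant to per-sample rescaling of all concentrations.
3. **FCBF selection.** Continuous features carry no entropy, so each feature
   is first discretized against the class by recursive binary splitting on
   information gain with the Fayyad–Irani MDL acceptance rule: a split of a
   node with N samples and class entropies H(S), H(S1), H(S2) over k, k1, k2
   classes is kept only if
   gain > [log2(N−1) + log2(3^k − 2) − (k·H(S) − k1·H(S1) − k2·H(S2))]/N.
   Features with no accepted split are uninformative, score SU = 0 and are
   dropped — this realises the "keep features scoring above 0" rule
   naturally. Remaining features are ranked by symmetrical uncertainty with
   the class and pruned by the predominant-feature rule (drop Fj when some
   kept Fi has SU(Fi, Fj) ≥ SU(Fj, class)). SU ties break by canonical
   feature order, so selection is deterministic. A `redundancy=False` switch
   exposes plain SU thresholding, since the original toolbox's behaviour
   (with or without redundancy elimination) is not documented.
4. **Univariate tables.** Per feature: Shapiro–Wilk on each group at
   α = 0.05; both normal ⇒ two-sided Student's t, otherwise two-sided
   Mann–Whitney (exact when combined n ≤ 20 without ties, else the tie- and
   continuity-corrected normal approximation). Effect summaries: group
   medians and IQR widths (linear-interpolation quantiles), absolute median
   difference, fold change = median(ref)/median(other) with the clinical
   reference group (BSI; Gram-negative) in the numerator, and
   %-difference = (fold − 1)×100. The source tables print two mutually
   inconsistent %-difference conventions; this one definition is fixed here
   and only fold changes are treated as checkable. Boxplot display trimming
   (values beyond 1.5·IQR from the quartiles) never feeds statistics.
5. **Demographic comparability.** Fisher's exact test (two-sided,
   probability-mass summation — the SPSS/R convention, which reproduces the
   published 0.022 and 0.699) when any expected 2×2 count is below 5,
   otherwise Pearson chi-square with Yates continuity correction (which
   reproduces the published ECMO p = 1.000; uncorrected gives ≈ 0.91).
   Screening threshold α = 0.01.
6. **Cross-validated classification.** Stratified five-fold CV (stratified
   because 7 Gram-negatives cannot otherwise populate five folds; the fold
   assignment is seeded and deterministic). Five families: kNN, random
   forest, SVM and decision tree delegate to scikit-learn defaults (no
   tuning is reported anywhere, and these families are not the headline);
   naive Bayes is the package's own categorical model over MDL-discretized
   bins with add-λ smoothing (λ = 1), matching the discretization used for
   selection and the binned nomogram intervals. AUC is computed on pooled
   out-of-fold positive-class scores (one summary per model, matching how a
   single CV value is usually reported; per-fold averaging is available);
   sensitivity and specificity come from pooled hard argmax decisions, with
   no threshold optimisation.
7. **Nomogram.** For the binary naive-Bayes model, each feature bin
   contributes points = ln P(bin | target) − ln P(bin | non-target)
   (natural-log scale; smoothing keeps every point finite), features listed
   in FCBF rank order. Because naive Bayes factorises, prior log odds plus
   the sum of a sample's bin points equals its posterior log odds exactly;
   the package asserts this identity to 1e-10. Output is numeric (a points
   table); no graphical chart is produced.

## Selection protocol and leakage

By default the pipeline selects features on the full dataset *before*
cross-validation — deliberately replicating the published protocol, whose
goal was biologically interpretable ratios rather than unbiased error
estimates, and which is leakage-prone by construction. The
consequence is quantified in the test suite: on label-permuted synthetic
cohorts the full-dataset protocol yields a mean pooled naive-Bayes AUC well
above 0.5, while nested per-fold selection (`nested_select=True`) stays at
0.5 ± 0.1 over 50 replicates. When a training fold selects nothing, the
evaluator falls back to the training-fold prior rather than failing.

## Synthetic cohort generator

**What it emulates.** Group sizes 23 / 7 / 15 (non-BSI / Gram− / Gram+; BSI
is the union of the Gram groups). Per cytokine and group, concentrations are
log-normal with location ln(median) and log-sd s = asinh(IQR/2m)/z₀.₇₅, so
the configured median is the distribution median and the configured IQR
width is exact. Default medians/IQRs are the published per-group summary
tables — the generator's default conditions are the real cohort's printed
location and spread. Concentrations are floored at 0.01 pg/mL (the assay is
high-sensitivity; ratios need positive denominators). Demographics (age,
gender, BMI, ECMO, IMV, comorbidities) follow the published marginal
frequencies per arm. Lab markers are log-normal with block-wise missingness
at the published per-group rates (82.6% non-BSI, 28.6% Gram−, 5% Gram+,
consistent with the 12.5% BSI-wide figure); CRP and PCT Gram-group medians
follow the published values, the remaining lab parameters are plausible ICU
magnitudes — lab markers exist to exercise missingness handling, not
inference. Equal seeds give byte-identical CSVs.

**Planted signal.** For signal-recovery experiments a ratio can be planted.
A naive implementation (shift each numerator cytokine's median) makes the
*individual* shifted cytokines the best features — a ratio is then never
the right answer. The generator instead emulates what makes ratio biomarkers
real: two co-regulated modules whose *balance* discriminates. Each side of
the planted ratio is drawn as a regulated module total (log-normal, log-sd
`planted_total_sigma` = 0.25, median = sum of the members' configured
medians, the numerator total ×`planted_effect` in the BSI arm) divided among
members by compositional shares (member log-weight sd `planted_share_sigma`
= 0.8). The full planted ratio equals the ratio of the module totals exactly
and is the least-noise realisation of the effect; every individual member
and every partial sub-ratio carries share noise the full ratio cancels.
Defaults were fixed at design time from the mechanism's rationale (a tightly
regulated total, several-fold member trade-offs).

**Signal-recovery experiment conditions** (as exercised in the tests):
uniform no-effect base of median 10 pg/mL and IQR 20 pg/mL — the
heavy-tailed IQR/median ratio of 2 is typical of the printed cohort tables —
planted effect ×4, n = 200 (100 / 35 / 65), 20 seeds. Under these conditions
FCBF ranks the planted ratio first in ≥ 90% of seeds and the pooled CV
naive-Bayes AUC exceeds 0.95.

**What it does not emulate.** No correlation structure beyond the planted
module (the real cytokine network is certainly correlated); no comorbidity
→ cytokine coupling; no batch effects or assay floor/ceiling censoring
beyond the fixed floor; demographics are independent of cytokines. Passing
tests therefore show the *pipeline* behaves correctly under the assumed
data model, not that the published cohort's specific AUCs (0.97 BSI /
0.983 Gram) would replicate — those depend on withheld raw data and are out
of scope.

## Numerical choices and degenerate inputs

* Entropies in bits; SU clamped to [0, 1] against float error; SU = 0 when
  both sequences are constant.
* MDL split search evaluates all distinct-value midpoints and takes the
  gain maximiser (first/lowest on ties); the vectorised multi-feature screen
  is arithmetic-identical to the per-feature recursion at the first split
  (asserted by test) and only prunes features that would receive no cuts.
* Quantiles are linear-interpolation (type 7) throughout; no convention is
  stated in the source.
* Fisher on a zero row/column margin returns p = 1 with a warning (the
  margins force the observed table); chi-square on a zero margin is an
  error.
* Mann–Whitney on two identical constant groups returns p = 1.
* Shapiro–Wilk is undefined for zero-range samples; such groups are routed
  to Mann–Whitney.
* Comparisons need ≥ 3 non-missing values per group; smaller groups are
  flagged and skipped in tables (mirroring lab-marker missingness) rather
  than silently dropped.
* `compare_groups` medians of an all-zero "other" group give an infinite
  fold change rather than an exception; cytokine inputs are positive by
  construction so this arises only for lab markers.
* The run manifest excludes wall-clock timings (logged instead) so equal
  seeds produce byte-identical manifests.

## Problem sizes in the test suite

Stochastic claims are tested at sizes chosen to make the statistics
decisive while the whole suite stays quick: median recovery at n = 10⁴ per
group (tolerance max(5%, 4 asymptotic SEs of a log-normal sample median —
the printed Table 4 IL-6 dispersion, IQR ≈ 3000× median, makes a flat 5%
unattainable at any desk n); signal recovery over 20 seeds at n = 200; null
calibration over 50 label-permuted 45-sample cohorts; selector-vs-oracle
agreement over 40 random tables of ≤ 8 features × ≤ 30 samples.

## Known limitations

* The FCBF/SU scores depend on the MDL discretizer; a different discretizer
  (equal-frequency, ChiMerge) would change rankings. The discretizer is the
  one the selection literature pairs with FCBF and the only one consistent
  with the "score 0 ⇒ drop" retention rule.
* With 19,250 features and 45 samples, full-dataset selection is
  optimistically biased by construction; nested selection is provided but
  the headline protocol is the leaky one, for fidelity.
* kNN/SVM/random-forest/decision-tree results use library defaults and are
  not comparable across library versions; only the naive-Bayes path is
  fully specified by this package.
* The nomogram covers binary targets only.
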