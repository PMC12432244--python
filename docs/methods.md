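# Methods

This note documents the statistical models behind `radsense`, the
parameters that matter, the synthetic-data generators used to validate
the pipeline, and the numerical choices made where the design was open.

## Candidate prioritization

The prioritization chain nominates genes that are simultaneously
(i) overexpressed in tumors relative to normal tissue, (ii) highly
expressed across a panel of tumor cell models, and (iii) associated with
shorter overall survival.

**Filtering and normalization.** Genes with zero total counts are
dropped, then genes with fewer than 1 count per million (CPM) in more
than 50% of samples; the cut is strict, so a gene low in exactly half of
the samples is kept. log2-CPM uses a prior count of 0.5 added to CPM
before the log to avoid −∞ (the offset choice only shifts
near-zero-expression genes). Cyclic loess normalization removes
intensity-dependent trends between samples: for every sample pair, the
loess trend of M = x_i − x_j on A = (x_i + x_j)/2 is subtracted half
from each sample, cycling over all pairs for 3 iterations at span 0.7.
These are conventional settings for this normalization family; the
O(n²) pair loop is acceptable at panel scale (tens of samples).

*Numerical choice:* with more than 500 genes the pair trend is fitted on
200 quantile-bin means of A and linearly interpolated, instead of an
exact loess through every gene. The MA trend is smooth at that scale, so
the approximation error is far below count noise, and the cost per pair
drops an order of magnitude. A loess smoother is a *contraction*, not a
projection: a noise-free constant offset is removed exactly in one pass
(and further passes change nothing), while on noisy data each cycle
shrinks the remaining trend geometrically rather than zeroing it. The
tests assert exactly that: fixed-point behavior on the noise-free case,
monotone contraction on noisy data, and < 0.01 residual mean offset
after normalizing a planted 1-log2-unit offset.

**Differential expression.** Per gene, a two-group one-way ANOVA on
log2-CPM, which for two groups equals the squared pooled-variance t
(asserted as an identity in the tests). Defaults |log2FC| > 0.3 and
p < 0.05 match the conventional tumor-vs-normal screening cutoffs. No
gene-length (TPM) normalization is performed: the pipeline standardizes
on log2-CPM throughout, so cross-gene expression comparisons carry a
length bias that cancels in all per-gene contrasts.

**High expression.** One-sample, one-sided t-test that a gene's mean
log2-CPM across cell models exceeds zero, on per-model replicate means
(so the test unit is the model, not the replicate), with
Benjamini–Hochberg FDR. A zero-variance gene gets p forced to 0 or 1
and a `degenerate` flag. Ranking for the top-N shortlist (default
N = 200) intersects up-regulated DEGs with the high-expression table
and orders by −log10(p) (ties: descending mean, then gene id); ordering
by expression magnitude is exposed as an alternative because either
reading is defensible, and with a planted signal both agree.

**Survival screen.** Per candidate gene, patients are split at the
median expression (ties go to "low", so "high" is strictly above the
median) and compared by the Mantel–Cox log-rank test, implemented
explicitly from the O/E/V sums because the screen needs the *direction*
of the excess events (high arm worse), which packaged implementations
do not expose; `lifelines` serves as an independent oracle in the test
suite, alongside a permutation null. Selection uses unadjusted p < 0.05
per gene plus the direction gate — the screen is a shortlist filter, not
an inferential endpoint, and the false positives it admits (~2.5% of
nulls) are controlled by the intersection with the other two gates.

**Overrepresentation.** Hypergeometric upper-tail p per gene set
restricted to the analysis universe, BH across sets. Sample clustering
uses 1 − Pearson correlation with Ward linkage on the precomputed
distances (the ward.D2 variant); labels are sorted before clustering so
exact ties merge deterministically.

## Screen scoring

Each knockdown × arm × endpoint condition in each cell model is scored
as −log10(p) × magnitude. For viability the magnitude is the SER of the
treated arm against the basal arm (in the basal arm itself, where SER is
undefined, control/knockdown is used so that killing scores above 1);
for damage/stress endpoints it is knockdown/control within the arm. The
p-value is a two-sided Welch t of knockdown vs control replicates —
robust to unequal variances at n = 3 — while the one-way ANOVA omnibus p
across genes is computed and reported alongside. p is floored at 1e-300
before the log. Direction is deliberately one-sided: protective effects
produce magnitudes below 1 and score low rather than being sign-flipped,
matching the screen's aim of finding sensitizers. The summary score is
the plain sum of condition scores over endpoints, arms and both cell
models (per-model subtotals are retained); this is the simplest
aggregation consistent with a two-model composite score, and the tests
only rely on its rank behavior, which is insensitive to the exact
aggregation among monotone choices.

## Radiobiology

Plating efficiency is colonies/seeded per replicate with mean ± SD
(ddof = 1); an assay with zero colonies in every replicate is flagged
"not countable" rather than treated as a measured zero. SF(d) =
PE(d)/PE(0). The SER is the single-dose ratio-of-ratios
(control treated/untreated) / (test treated/untreated), the only
well-defined enhancement ratio when the screen uses one dose point
(4 Gy); dose-modifying-factor definitions need full survival curves and
are out of scope. SER is invariant to common rescaling of all arms.

Bliss independence operates on fractional inhibitions
f = 1 − treated/control ∈ [0, 1]; negative values (stimulation) clamp to
0 with a warning. The excess f_observed − (f_A + f_B − f_A·f_B) gets a
seeded bootstrap percentile CI (default 2000 resamples over replicates);
the call is synergistic/antagonistic only when the CI excludes zero,
with a 1e-9 guard so exact-zero excess is never misclassified by float
round-off. With planted zero excess the synergistic call rate stays
within binomial error of the nominal 2.5% one-sided level (asserted over
200 simulations).

## Metabolomics

Feature annotation accepts a library entry when the ppm mass error is
≤ 10, |ΔRT| ≤ 0.3 min (if the library has an RT) and the relative CCS
deviation is ≤ 3% (if present); the best match minimizes (ppm, ΔRT,
ΔCCS) lexicographically with the metabolite name as final tie-break, so
the result is independent of library row order. Comparisons carry a
1e-9 *relative* guard so deviations constructed to sit exactly on a
boundary are accepted despite float round-off; 10.01 ppm remains
rejected by six orders of magnitude. Adducts and isotopes are out of
scope: the library m/z is taken as the observed ion species.

Differential abundance is a two-sided t-test on log10 intensities
(the transform that makes lognormal intensities normal; a generalized
log is available for zero-containing data), with fold change as the
ratio of raw group means and the contrast — which group against which
control — always an explicit argument, never defaulted. No multiple-
testing correction is applied by default (raw p < 0.05 at n = 4 is the
operating convention for this readout); BH is available via a flag.
Targeted peak-area tables run through the same operations. Pathway
impact is the percentage of measured pathway members significantly up or
down; with no correction, a null pathway of m members shows ~5%·m
significant by chance, which the calibration tests quantify.

PLS-DA is a hand-written NIPALS loop — autoscaled X, centered one-hot
response, score iteration started from the first response column,
tolerance 1e-10, ≤500 iterations — because the method must be exactly
reproducible run to run; `scikit-learn`'s PLS is the cross-check oracle
in the tests (component scores correlate > 0.99). Constant columns are
dropped with a notice. Note that supervised projections overfit: with
20 samples and 50 variables, even permuted labels yield in-sample
silhouettes near 0.5, so the permutation control asserts that the true
separation exceeds every permuted one, not that permuted separation is
zero. Out-of-sample validation is the user's responsibility.

## Lipid peroxidation

Per-cell ratio oxidized/non-oxidized emission; cells with zero 590 nm
signal are excluded with a warning (they carry no ratio information).
Condition summaries expect 50 cells per condition by assay convention
and warn otherwise. Comparison is one-way ANOVA with either Tukey HSD
(all pairs) or the exact Dunnett many-to-one procedure against a named
control; both come from scipy. Background subtraction is the caller's
responsibility. Both raw and control-normalized ratios can be reported
(normalization is a single `normalize_to_basal` call).

## Synthetic data and what passing tests show

Generators are pure functions of (arguments, seed); sub-streams per
table derive from one 64-bit seed, so equal seeds give byte-identical
tables.

- **Counts**: negative binomial with dispersion 0.1 (typical bulk
  RNA-seq overdispersion) around lognormal gene baselines, library
  sizes uniform in 0.8–1.2 M. Planted DEGs multiply the tumor mean by
  2^log2FC.
- **Survival**: exponential event times with baseline median 14 months
  (typical GBM overall survival); a latent binary risk group carries
  hazard_ratio × the baseline hazard and independent censoring trims
  the stated fraction of events. Planted prognostic genes are elevated
  in risk-group patients, so their median splits concord with the
  latent group — co-expression of prognostic genes is what makes a
  per-gene median-split screen with many planted genes coherent; with
  independent per-gene hazards the marginal effect of any one gene
  would vanish.
- **Screen / metabolome / lipid**: lognormal replicate noise with a
  stated CV around control-relative means (mean-preserving
  parameterization for the screen and metabolome; geometric-mean
  parameterization for the lipid ratios, whose natural summary is the
  geometric mean). Functional assays default to n = 3 replicates,
  metabolomics to n = 4.
- **Clonogenic**: colonies ~ Poisson(seeded · PE₀ · exp(−αd − βd²)),
  capped at the number seeded.
- **Metabolome features**: a configurable fraction (default 80%) are
  true library matches perturbed *within* 60% of each tolerance; decoys
  are pushed 2–5× beyond every tolerance, so truth-sheet concordance of
  the matcher is exact by construction.

The generators emulate replicate noise, planted effect sizes and the
multiplicity structure of the real assays. They do **not** emulate
batch effects, gene–gene correlation beyond the planted risk factor,
heavy-tailed outliers, missing values, adduct/isotope ambiguity, or
drift — so passing recovery tests demonstrates that the chain is
correctly implemented and calibrated under its stated assumptions, not
that it is robust to every pathology of real data.

**Validation study sizes** (chosen once as a desk-scale design): the
end-to-end recovery study uses 2000 genes with 100 planted
triple-positive candidates (log2FC = 1, high panel expression, hazard
ratio 2.5), tumor/normal cohorts of 12 vs 12, a panel of 8 models × 3
replicates, and 150 patients with 30% censoring, averaged over 20
seeds; the pipeline recovers ≥ 90% of planted genes with ≤ 5% false
discoveries. Null-calibration and false-call rates use 200 simulations;
ranking recovery uses 100 simulated screens.

## Known limitations

- Cyclic loess assumes most genes are non-differential between any two
  samples; heavy asymmetric differential expression biases it.
- The survival screen is a log-rank on a median split only — no Cox
  modeling, no covariates, no adjustment for multiple candidate genes.
- The summary-score aggregation (plain sum over conditions) is one of
  several defensible composites; rank stability across monotone
  alternatives is tested, absolute score values are not comparable
  across screens with different numbers of conditions.
- LC-MS annotation is tolerance matching against a user-supplied
  library; no MS/MS fragment scoring, no adduct resolution.
- PLS-DA reports in-sample separation; use held-out data or the
  permutation comparison for honest effect assessment.
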