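# Methods

This note documents the models, rules, parameters and numerical choices
behind `cnagain`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Copy-number model and geometry

Input copy numbers are **ploidy-normalised log2 ratios**: the segment log2
ratio adjusted for sample ploidy, so every call is relative to the sample's
overall ploidy rather than to an absolute copy count. Data supplied as raw
log2 ratios can be converted with `genome.normalize_ploidy`
(cn − log2(ploidy/2)).

Coordinates are 0-based half-open internally; SEG input is treated as 1-based
inclusive by default with a dialect flag, because interval arithmetic on
half-open intervals is unambiguous.

Bins tile each chromosome from 0 in `bin_size` steps, with **both**
centromere boundaries inserted as extra cut points so no bin spans the two
arms; the centromere-interior bin is retained and is typically missing-valued
(segmented profiles rarely cover it). An alternative per-arm tiling (each arm
restarts at its own origin) is available as a switch; the two differ only in
where q-arm bin edges fall. The bin copy number is the overlap-weighted mean
of segment values, and the covered fraction is always carried; no minimum
coverage is imposed for reporting a value — callers filter on
`covered_fraction` as appropriate.

## Call rules

All thresholds use strict inequalities; a value exactly at a threshold falls
in the lower category (deterministic, and consistent with "higher than"
phrasing). Defaults, configurable per dataset:

| parameter      | default | meaning |
|----------------|---------|---------|
| `t_gain`       | +0.1    | log2 ratio above which a bin/gene is gained |
| `t_loss`       | −0.1    | log2 ratio below which it is lost |
| `arm_fraction` | 0.8     | fraction of *covered* arm length above `t_gain` for an arm-level gain |
| `amp_fallback` | +0.9    | absolute amplification threshold for samples with no gained arm |

The arm-gain denominator is the covered length, not the full arm length, so
partially profiled arms are judged on the data available. The amplification
rule is sample-relative — gene copy number strictly above the sample's
highest whole-arm-gain mean — with `amp_fallback` covering samples that have
no gained arm (the relative rule is undefined there). Gene status precedence
is amplification ≻ arm_gain ≻ focal_gain ≻ loss ≻ neutral; a gene below
`t_gain` on a gained arm stays neutral, because the call describes the gene's
own copy number, not its arm's.

Frequency z-scores standardise each bin's gain (loss) frequency against the
mean and standard deviation across bins within the cohort. This cross-bin
standardisation is a stated approximation: it answers "which bins are
unusually often gained relative to the genome-wide distribution" and is not a
calibrated null model.

## Association testing

"Student's t-test" is implemented as the **unequal-variance (Welch)** form by
default — the default of the statistical environments these analyses are
usually run in — with a pooled-variance switch. The dependency contrast
compares low-amplitude gain (arm-level + focal combined, or arm-only)
against neutral lines; loss and amplification lines belong to neither group.
The drug contrast compares low-amplitude gain against "no gain"
(neutral + loss), excluding amplified lines, mirroring the three-way
classification used for drug analyses. The implementation computes the test
vectorised across genes (masked group moments and the t survival function);
tests verify exact agreement with `scipy.stats.ttest_ind` on random small
groups.

**q-values** follow Storey's construction: π0 estimated by a cubic-polynomial
smoother of π0(λ) over λ ∈ {0.05, …, 0.95} evaluated at the largest λ, then
q(i) = π0·m·p(i)/i monotonised from the largest p down. With fewer than 100
p-values, or when the smoother is unstable, the method falls back to
Benjamini–Hochberg (π0 = 1), which is conservative. At a pure null this keeps
the fraction of q < 0.1 calls near zero; note that q < α on a set of
discoveries *bounds the expected false fraction* — individual null features
can and occasionally do cross any q threshold.

**Ranking and enrichment.** Genes are ranked by `sign(Δ)·(−log10 q)` (zero q
clamped to the smallest positive float; ties broken by |Δ| then gene label so
the order is reproducible). Gene-set enrichment uses the weighted
Kolmogorov–Smirnov running sum with weight |metric| (exponent 1). Because
only a ranked list is available, the null is **gene-label permutation**:
random same-size sets, `n_perm` seeded draws. NES divides the enrichment
score by the mean |ES| of same-sign permutations; the p-value is
`(1 + #{more extreme same-sign}) / (1 + #{same-sign})`. Negative NES means
enrichment at the negative (more-dependent-when-gained) end.

**Candidate selection** lists genes with q < 0.3 and Δ < −0.05 in at least 2
of the supplied datasets; the thresholds are configuration values. Mutation ×
gain co-occurrence uses Fisher's exact test (no test is canonical here;
Fisher handles small cells exactly). Expression checks are one-sided
(gain > neutral) because the claim being tested is directional. The
confounder filter removes genes whose combined experimental-confounder
importance (an input table from an external dependency-prediction model)
strictly exceeds 0.05; genes absent from the table are retained and logged.

## Elastic net

Per compound, AUC is modelled from binary features: mutations, per-bin gain /
loss / amplification indicators (amplification encoded independently of
gain), and one-hot cancer type/subtype. The response is centred; binary
predictors are left unstandardised so indicator coefficients remain
interpretable (a switch standardises). The mixing grid is {0.1, 0.5, 0.9}
with the CV-chosen value; the penalty strength is chosen by the **one-SE
rule** (strongest penalty within one standard error of the CV-minimum).
The one-SE default is deliberate: replicates share the data and differ only
in fold assignment, so the CV-minimum model's dozens of small noise
coefficients survive replicate intersection essentially unchanged, and the
"features present in all replicates" report loses its meaning. Under the
one-SE rule the triplicate intersection recovers planted effects with at most
a couple of extras. `cv_min` remains available in the configuration.
Selection is bit-reproducible given (config, seed). Each reported feature is
separately tested in an OLS ANOVA containing only cancer type, subtype and
that feature (type-II p for the feature term); features exactly collinear
with the type/subtype design are flagged untestable.

## Survival

Per bin, a univariate Cox proportional-hazards model is fitted on the binary
gain indicator and, separately, the loss indicator (matching the
positive/negative split of per-CNA association plots); no covariates are
included by default. Ties use the Efron approximation (lifelines default).
Bins with a constant indicator or fewer than 3 samples on either side are
untestable; cohorts need ≥10 events. The signed survival score is `HR` for
HR ≥ 1 and `−1/HR` for HR < 1 (HR = 1 maps to +1), an odd-symmetric transform
that places protective and harmful effects on the same scale with
|score| ≥ 1.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
the biology of real genomes. Toy genome: 4 chromosomes of 120 Mb with
centromeres at 55–65 Mb — large enough to separate arm-level from focal
events at 25-Mb and 1-Mb binning, small enough for brute-force per-position
oracles. Per sample, each arm gains with probability 0.15 or loses with 0.10;
focal gains (Poisson mean 0.8/sample, lengths 2–20 Mb) and amplifications
(mean 0.1/sample, 1–5 Mb) overlay additively; copy levels are +0.3 / −0.3 /
+1.2 with Gaussian segment noise of sd 0.1 on the log2 scale; passenger
breakpoints (mean 2/arm) exercise the weighted-mean logic. All breakpoints
are drawn on a 100-kb lattice, which makes per-100-kb brute-force oracles
*exactly* equal to per-base arithmetic.

Downstream matrices plant effects at the magnitudes the pipeline is designed
to detect: a dependency ladder of −0.28 (focal) / −0.44 (arm) / −0.64
(amplification) versus neutral with score sd 0.3; a drug AUC shift of −0.11
on one compound (baseline 0.5, sd 0.15); a mutation–gain odds ratio of 2.2
(rates solved numerically to preserve the marginal mutation rate); and an
exponential survival model with hazard ∝ exp(Σ β·indicator), independent
exponential censoring calibrated to a ~40% baseline event rate. Every planted
effect is recorded once in a machine-readable truth ledger; recovery tests
consume only the ledger. Everything is bit-reproducible under a fixed seed.

What the generator does **not** emulate: realistic breakpoint processes,
whole-genome doubling, heavy-tailed segment noise, correlated gene
dependencies, batch structure across screens. Passing recovery tests
therefore demonstrates contract correctness of each stage under idealised
noise, not performance on real cohorts.

## Validation experiment sizes and statistical framing

The validation suite (`cnagain.validation`, exercised by the tests and
`scripts/acceptance.py`) uses: 1000 profiles for the geometry oracle; 1000
arms (with 20% of segments dropped to create partial coverage) for the
arm-rule oracle; 20 cohorts of 100 lines/class for ladder recovery; 20 × 2000
genes for null FDR; 10 × 3 datasets of 500 genes for candidate selection;
2000-gene ranked lists (1000 permutations) for planted enrichment and 100
null repetitions for p-uniformity; 400 lines × 200 compounds for drug
recovery; 200 lines × ~320 features for elastic-net stability; and 10 cohorts
of 300 patients for survival recovery.

Two point estimates are reported as means over replicate cohorts rather than
single draws, because their single-cohort sampling error is comparable to the
recovery tolerance: the dependency-ladder deltas (se ≈ 0.042 per cohort
against a ±0.1 tolerance; every cohort must still individually give p < 0.01
and monotone means) and the Cox hazard ratio (se of log HR ≈ 0.18 at n = 300;
the log-scale mean over 10 cohorts is reported with the median per-cohort p).
This is an estimator-replication choice, not a widened tolerance.

## Known limitations

- With segment noise sd equal to the call thresholds (both 0.1), ~16% of
  truly neutral gene values cross each threshold, and a gene on a sample's
  only gained arm exceeds that arm's mean (hence the sample-relative
  amplification rule) about half the time. End-to-end recovery through
  *called* statuses is therefore attenuated relative to module-level recovery
  through true statuses — visible in the README worked example. Real
  segmented data have longer, more stable segments; per-dataset thresholds
  should be calibrated to the platform.
- The z-score track is a cross-bin standardisation, not a null-calibrated
  significance measure.
- The GSEA null permutes gene labels; it cannot capture inter-gene
  correlation, which would require sample-level permutation of the upstream
  tests.
- Univariate Cox models carry no clinical covariates; the configuration
  exposes adjustment but the defaults are unadjusted.
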