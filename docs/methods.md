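# Methods notes

This note records the statistical models, the conventions chosen where the
underlying methodology leaves genuine freedom, the simulator's assumptions,
and the limits of what the test suite demonstrates.

## Genotype model and codings

Genotypes are stored as minor-allele dosages 0/1/2 with an explicit missing
code. For PLINK-style `.ped` input the minor allele is determined per marker
from the pooled allele frequency (ties broken to the lexicographically later
allele), so all downstream statistics are invariant to which strand or
allele a file happens to report — a property the test suite checks directly
(trend P unchanged, allelic OR inverted, LD r² unchanged under relabelling).
The TSV dialect is already dosage-coded and is read verbatim, which keeps a
write→read round trip exact. Dominant coding marks carriers ({1,2}) as
exposed; recessive marks minor-allele homozygotes ({2}).

LD is the composite (dosage-correlation) r²: squared Pearson correlation of
dosage vectors over pairwise-complete samples. Data are unphased and no EM
phasing step is assumed; for pruning purposes the composite measure is the
standard choice. Constant markers yield an undefined (NaN) r², deliberately
distinct from 0.

**Top-list pruning.** Published top-10 tables keep one marker paired with
several different, mutually uncorrelated partners. The pruning rule here
therefore treats a candidate pair as redundant only when *both* of its
markers are in LD (r² > 0.2, identical markers counting as 1) with the
markers of an already-kept pair, under either alignment of the two slots.
Dropping on a single shared marker would contradict how such tables are
actually presented.

## Pair tables and preventive-factor recoding

A pair under one coding collapses to case/control counts in cells
00/01/10/11, complete-case per pair (samples missing either genotype are
dropped; this reproduces the small per-pair fluctuations in published
totals). Before additive statistics are computed, cell labels are permuted
so that both single-exposure odds ratios versus the new 00 cell are ≥ 1.
The available schemes are identity and the three published relabellings
(flip marker 1; swap markers then flip the new marker 2; flip both). When
several succeed the first in that fixed order is taken — the source material
states no preference, and a deterministic order makes results reproducible.
When none succeeds, the scheme maximizing min(OR01, OR10) is applied and
the table is flagged. Recoding is a pure relabelling: counts are conserved,
and applying it twice is a no-op whenever the postcondition was achieved
(the four schemes are not closed under composition, so idempotence is only
guaranteed in the non-flagged case; the property test is scoped
accordingly).

## Additive interaction (RERI / AP)

On an all-positive 2×2×2 table the saturated logistic MLE equals the
cross-product odds ratios, so the fit is closed-form; an iterative GLM is
kept in the tests as an independent oracle (agreement to six significant
figures). The AP variance follows the Hosmer–Lemeshow delta method on
(β1, β2, β3), whose covariance is assembled from the independent cell
log-odds variances 1/cases + 1/controls. The two-sided P is taken from
z = AP/se(AP) — the convention on AP rather than RERI, which reproduces the
published CIs to ~2 decimals and the headline P to within ~2% in spot
checks; exact equality with every published P is not claimed, since the
original variance estimator is not documented. Zero cells receive a 0.5
continuity correction (flagged); any cell below 5 raises a small-cell flag.

AP is reported unclipped. Values below −1 arise mechanically when the
denominator OR11 is small — i.e. for negatively interacting pairs — and
concentrate where an exposure cell is nearly empty or one single-exposure
OR is large. `ap_diagnostics` tabulates AP against the minimum cell count
and the smaller/larger single-exposure OR (with correlations restricted to
AP < 0) so this pathology can be inspected rather than silently truncated.

## Multiplicative interaction

exp(β3) = OR11/(OR01·OR10), Wald SE = sqrt of the summed reciprocals of the
eight cells, two-sided Wald P. The Wald (not likelihood-ratio) convention is
used because it is what the published interaction P values correspond to.
Protective interaction ORs (< 1) are reported as fitted, never inverted.

## MDR

Missing genotype is a genuine category (4×4 grid for a pair, 4³ for a
triple), so classification counts always add up to the full sample. A cell
is high-risk when its training case:control ratio reaches T = overall
training cases/controls; non-empty cells with zero controls are high
(ratio = ∞), fully empty cells low. Reported table metrics (balanced
accuracy, OR with Wald CI, Pearson chi-square P, TPR/FPR) are computed on
the full data, which is how published MDR rows are exactly reproducible
from their high/low counts. Cross-validation uses stratified 10-fold splits
under a fixed seed (the original fold construction is unstated); ranking
uses the testing balanced accuracy with full-data accuracy as tie-break,
and both are exposed. CVC counts the folds in which a combination attains
the best training balanced accuracy, with one deterministic winner per
fold.

## Single-marker stage

Cochran–Armitage trend test with scores (0,1,2) in its large-sample form
(z² = N·num²/den); the tests verify it against the individual-level
identity z = r·√N with r the dosage–status Pearson correlation. No
covariates are fitted: the simulated populations carry no structure, so
principal-component adjustment would model noise; this is a deliberate
omission relative to covariate-adjusted pipelines used on real cohorts.
Meta-analysis pools per-study allelic 2×2 tables: Woolf's inverse-variance
Q decides between the Mantel-Haenszel fixed-effect pool (statsmodels,
Robins-Breslow-Greenland SE) and a DerSimonian-Laird random-effects pool
(computed directly, with τ² truncated at zero); the pooled P is a Wald test
on the pooled log-OR, the reporting convention that matches how pooled
results are quoted.

## Scan engine

Seed prioritization unions markers with trend P < 0.05 and the top-k
markers by ReliefF relevance among the remainder. ReliefF is implemented
in-package (k = 10 nearest hits/misses under a normalized Manhattan dosage
distance, probe subsampling for large n) as the representative of the
filter family shipped with MDR software; it is deliberately swappable.
`seeds_x_all` enumeration reports both the raw evaluation count
(|seeds| × |markers|, the bookkeeping figure quoted for such scans, which
includes self and duplicated seed-seed pairs) and the unique unordered pair
count actually tested.

Permutation correction permutes phenotype labels B times, re-scans, and
records the best statistic per permutation (−log10 P for regressions;
full-data balanced accuracy for MDR, since re-running cross-validation
inside every permutation is computationally disproportionate and the
max-statistic logic is unchanged). Permuted P uses the add-one estimator
(1 + #{best ≥ observed})/(B + 1), which cannot return zero and is slightly
conservative; the FWER threshold is the 95th percentile of the
permutation-best distribution. Regression scans run on a vectorized path
(per-pair cell indicators × permuted status vector), and a dedicated test
pins the vectorized statistics to the reference per-table fits.

The 0.5% top region is defined per method on its own ranking statistic, and
cross-method agreement is the Pearson correlation between the top-q records
of one method and the full table of another, joined on unordered pair keys.

## Classifier metrics

AUC is computed from the grouped exposure categories ordered by their
case:control odds (ties contribute ½) — the grouped Mann-Whitney
concordance, which is what published per-pair AUC values correspond to, not
a fitted-probability ROC. PAF uses the Miettinen case-load form
PAF = Σ pc_i·(OR_i − 1)/OR_i over non-baseline categories (equivalently
1 − Σ pc_i/OR_i). The exact PAF convention behind the published per-pair
values is not documented in the available material and their magnitudes are
not reproduced by the standard forms, so published PAF numbers are not an
acceptance surface here; the implemented estimator is labelled for what it
is.

## Simulator

The generator emulates the modelled study's design: fixed case/control
quotas (defaults 1,732/1,783), 3,704 markers grouped into 63 gene labels,
HWE genotypes with per-marker MAF uniform on (0.05, 0.5], baseline
prevalence 15% (a common-disease setting), independent markers (no LD by
default), and independent missingness. Disease status is assigned from the
configured risk model and sampled by rejection to the exact quotas, because
the case-control design fixes group sizes by construction. Main and
multiplicative effects act on the logit; additive-pair effects specify
exposure-category risks on the risk-ratio scale
R00·[1 + (ORa−1)xa + (ORb−1)xb + RERI·xa·xb] (the scale on which AP is
defined); epistatic grids give penetrance directly. Configurations implying
risks above 1 are rejected.

Because sampling is case-control, odds-scale estimators converge to the
odds-scale functionals of the generating risks. For an additive pair the
truth record therefore stores both the risk-scale target AP and the implied
odds-scale AP; at 15% prevalence the two differ noticeably (the OR/RR
inflation long noted for additive interaction measures in common diseases),
so CI-coverage checks target the odds-scale estimand, while risk-scale
recovery is demonstrated under a rare-disease configuration where OR ≈ RR.

What the simulator does *not* emulate: haplotype/LD structure from
reference panels, population stratification or any covariate confounding,
genotyping batch effects, and informative missingness. Tests passing on
simulated data therefore validate the estimators and the scan machinery,
not robustness to those real-data complications.

## Problem sizes and numerical conventions

The test suite runs the statistical calibration checks at the sizes chosen
for them: AP CI coverage over 500 replicates at n = 5,000/5,000;
multiplicative type-I error over 2,000 replicates at n = 1,000/1,000; MDR
detection of an XOR pair among 30 null markers over 50 runs at
n = 1,000/1,000; permutation FWER calibration over 100 null datasets of 20
markers with B = 200. Pipeline smoke tests use a few hundred markers.
Tolerances on simulated calibration quantities are 3-sigma binomial bands
around their nominal values. All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; reported tables round AP/OR to 2
decimals, balanced accuracy and AUC to 4, and P values to scientific
notation, matching the source-table conventions so golden-row comparisons
are direct.

## Known limitations

Binary PLINK (.bed), BGEN, phasing and imputation are out of scope; LD r²
is composite, not haplotype-based; regressions fit no covariates; MDR is
limited to 2- and 3-way models; the permutation engine re-runs scans under
label permutation only (no genotype permutation schemes); and AP inference
on very sparse tables (cells < 5) should be read with the small-cell flag
in hand — the delta method is a large-sample device and the negative-AP
diagnostic exists precisely because it degrades gracefully but visibly.
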