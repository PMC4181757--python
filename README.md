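# episcape

Pairwise SNP–SNP interaction analysis for case-control genotype data.

`episcape` is aimed at statistical geneticists and epidemiologists who want
to scan candidate-gene panels for two-locus (epistatic) effects on disease
risk, the way it is done in candidate-gene studies of complex psychiatric
disorders such as major depressive disorder: a panel of a few thousand
biallelic autosomal markers, a couple of thousand cases and controls, and no
single method trusted to capture every form of interaction. The package
implements the three complementary definitions of statistical interaction,
the machinery to run them as exhaustive pairwise scans with family-wise
error control, and a simulator that generates case-control datasets with
known planted interactions so every stage is testable without any genotype
download.

## Methods at the core

Each marker is collapsed to a binary exposure under a **dominant** (dosage
{1,2} exposed) or **recessive** ({2} exposed) coding. For a pair of
exposures A and B with odds ratios OR01, OR10, OR11 relative to the
doubly-unexposed cell:

* **Additive scale** — relative excess risk due to interaction and the
  attributable proportion,

      RERI = OR11 − OR01 − OR10 + 1,        AP = RERI / OR11,

  with a delta-method variance (Hosmer–Lemeshow) on the saturated logistic
  coefficients, a 95% CI and a two-sided z test. Before the additive fit,
  cell labels are permuted by one of four fixed schemes so both single
  exposures confer risk ("preventive-factor recoding"); the scheme used is
  reported. AP is never truncated: strongly negative values (even below −1)
  are reported and a dedicated diagnostic relates them to sparse exposure
  cells and large single-exposure ORs.

* **Multiplicative scale** — the product-term coefficient β3 of
  `logit P(case) = β0 + β1·A + β2·B + β3·A·B`, with
  exp(β3) = OR11/(OR01·OR10), Wald SE `sqrt(Σ 1/cell)` over the eight cells
  and a two-sided Wald P.

* **Model-free (MDR)** — multifactor dimensionality reduction: each
  two-locus genotype cell (missing genotype is its own category) is labelled
  high-risk when its case:control ratio reaches the sample-wide ratio; the
  resulting binary classifier is scored by balanced accuracy, with 10-fold
  stratified cross-validation, cross-validation consistency (CVC),
  classification OR with chi-square P, and TPR/FPR.

Around these sit: Cochran–Armitage trend tests and a Mantel-Haenszel /
DerSimonian-Laird meta-analysis (after Woolf's heterogeneity test) for
single markers; seed-marker prioritization (main-effect P < 0.05 plus a
ReliefF relevance filter); max-statistic permutation FWER correction;
category-concordance AUC and population attributable fraction per pair; and
composite-LD (r²) pruning of top-10 tables.

## Worked example

```python
from episcape import (EffectSpec, SimConfig, simulate, build_table,
                      recode_preventive, additive_fit, multiplicative_fit,
                      mdr_evaluate, auc_from_table)

cfg = SimConfig(
    n_cases=1500, n_controls=1500, n_markers=50, missing_rate=0.01,
    effects=[EffectSpec("multiplicative_pair", (0, 1), coding="dominant",
                        or_a=1.2, or_b=1.2, or_interaction=2.5)],
    seed=42,
)
res = simulate(cfg)
pair = ("sim1", "sim2")
t = build_table(res.genotypes, res.phenotype, pair, "dominant")
mult = multiplicative_fit(t)
add = additive_fit(recode_preventive(t))
mdr = mdr_evaluate(res.genotypes, res.phenotype, pair, seed=42)
print(f"interaction OR exp(b3) = {mult.or3:.2f} "
      f"({mult.or3_ci[0]:.2f}:{mult.or3_ci[1]:.2f}), P = {mult.p_value:.2E}")
print(f"AP = {add.ap:.2f} ({add.ap_ci[0]:.2f}:{add.ap_ci[1]:.2f}), "
      f"P = {add.p_value:.2E}")
print(f"MDR balanced accuracy = {mdr.ba_full:.4f}, CV = {mdr.ba_cv:.4f}, "
      f"OR = {mdr.odds_ratio:.2f}")
print(f"AUC = {auc_from_table(t):.4f}")
```

prints

```
interaction OR exp(b3) = 2.31 (1.68:3.17), P = 2.39E-07
AP = 0.59 (0.48:0.69), P = 1.85E-28
MDR balanced accuracy = 0.6250, CV = 0.6243, OR = 3.16
AUC = 0.6373
```

The planted interaction OR of 2.5 is recovered as 2.31 with a tight CI; the
same pair shows strong additive-scale synergy (AP = 0.59: about 59% of the
doubly-exposed group's excess odds is attributable to the interaction); MDR
flags the pair with a cross-validated balanced accuracy well above the null
0.5; and the four-category risk score separates cases from controls with
AUC 0.64.

The same pipeline is scriptable from the shell:

```sh
episcape simulate --seed 42 --out data.tsv
episcape assoc data.tsv --out assoc.tsv
episcape scan data.tsv --method multiplicative --coding dominant --out scan.tsv
episcape permute data.tsv --method multiplicative -b 1000 --seed 42 --out perm.tsv
episcape run --seed 42 --out-dir results/            # full pipeline
```

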