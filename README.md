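# isletpheno

Analysis pipeline for **nutrient-stimulated insulin secretion phenotyping of
human islet donor cohorts**, paired with **multi-omic (proteome /
transcriptome) association analysis** — and a synthetic-cohort generator that
makes every stage testable end-to-end without access to donor data.

Isolated human islets perifused with carbohydrate (15 or 6 mM glucose),
amino acid (5 mM leucine), or fatty acid (1.5 mM oleate/palmitate) stimuli
secrete insulin with stimulus-specific kinetics: biphasic for glucose and
leucine (a first-phase burst over ~15 min, then a sustained second phase),
monophasic for fat, and a sharp transient for KCl depolarization.  Donors
vary widely; a small subpopulation are *hyper-responders* whose fat (or
leucine) response exceeds their 15 mM glucose response, and islets from type
2 diabetic (T2D) donors show stimulus-specific secretion deficits.  This
package implements, as reusable estimators and functions:

- **Perifusion feature extraction** — unit conversion to pmol·islet⁻¹·min⁻¹
  (`rate = concentration × flow / islets`), baseline-subtracted trapezoidal
  segment AUC, first/second-phase decomposition (first 15 min vs remainder),
  peak rate and time-to-peak within the first 15 min of a solution change.
- **Hyper-responder classification and group contrasts** — the strict rule
  AUC(nutrient at basal glucose) > AUC(15 mM glucose), Clopper-Pearson
  prevalence CIs, Welch *t* / Mann-Whitney contrasts with
  Benjamini-Hochberg (BH) control.
- **Omics preprocessing** — >50%-missingness filter, per-donor median /
  log₁₀ normalization, deterministic k-nearest-neighbour feature-regression
  imputation; RNA low-count filter (<5 counts in >50% of donors),
  log₂(CPM+0.5), per-batch location/scale standardization.
- **Association** — per-feature t-test differential abundance (log₂ fold
  change, BH q) and covariate-adjusted OLS (`abundance ~ trait + T2D`).
- **Concordance** — across-gene and within-gene RNA-protein correlation,
  rank-rank hypergeometric overlap (RRHO) grids, and hypergeometric
  over-representation analysis against GMT gene sets.
- **Signed weighted co-expression networks** — biweight midcorrelation,
  signed soft-threshold adjacency `a_ij = ((1+cor_ij)/2)^β` (β = 8 proteome,
  20 RNA), topological overlap (TOM), average-linkage clustering with a
  static cut, module eigengenes (oriented first principal components), and
  module-trait partial Pearson correlation adjusted for technical isolation
  covariates.
- **Marker-based composition** — first-PC marker scores per islet cell type
  (alpha/beta/delta/acinar) with ND-vs-T2D contrasts.

The synthetic cohort generator (`isletpheno.simulate`) plants all of this
structure — responder mixtures, T2D effect multipliers, co-expression
modules coupled to secretion traits, differential features, batch effects,
abundance-dependent missingness — at configurable values, and records every
latent draw in ground-truth tables so recovery can be verified.

## Worked example

```python
from isletpheno.simulate import GeneratorConfig, simulate_cohort
from isletpheno.perifusion import build_feature_table
from isletpheno.responders import (classify_hyper_responders, prevalence,
                                   t2d_effect_summary)

bundle = simulate_cohort(GeneratorConfig(seed=1), omics=False)   # 123 ND + 17 T2D
features = build_feature_table(bundle.traces, bundle.protocols)
calls = classify_hyper_responders(features)
for cls in ("fat_hr", "leu_hr"):
    frac, (lo, hi) = prevalence(calls, cls)
    print(f"{cls}: {100*frac:.1f}% (95% CI {100*lo:.1f}-{100*hi:.1f}%)")
table = t2d_effect_summary(features, bundle.donors)
print(table[table.feature.str.endswith(":auc")]
      [["feature", "percent_difference", "p", "q"]].round(3).to_string(index=False))
```

prints

```
fat_hr: 10.0% (95% CI 5.6-16.2%)
leu_hr: 6.4% (95% CI 3.0-11.9%)
        feature  percent_difference     p     q
        fat:auc              64.496 0.000 0.000
fat_plus_g6:auc              65.589 0.000 0.000
  glucose15:auc              32.970 0.000 0.000
   glucose6:auc              33.011 0.000 0.000
        kcl:auc              27.373 0.000 0.000
leu_plus_g6:auc              38.825 0.000 0.000
    leucine:auc              18.719 0.016 0.022
```

For this one cohort draw, 10.0% of donors are classified as fat
hyper-responders (the generating prevalence is 8%; a 140-donor cohort has a
binomial sampling width of ±2-5 points), and T2D donors secrete ~33% less
insulin in response to 15 mM glucose (`percent_difference` is
100·(1 − mean_T2D/mean_ND) of the baseline-subtracted segment AUC).
Averaged over many seeds these estimates converge to the configured
population values — that convergence is what `scripts/acceptance.py`
measures.

The same stages are available from the shell:

```bash
isletpheno simulate --out cohort/ --seed 1
isletpheno features --traces cohort/ --out features.tsv
isletpheno classify --features features.tsv --out calls.tsv
isletpheno run --out run/ --seed 1       # full pipeline + markdown report
```

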