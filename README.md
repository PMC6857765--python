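# duomr

Two-sample Mendelian randomization (MR) for **maternal** exposures on
**offspring** outcomes, with SNP–outcome associations partitioned into
maternal-specific and fetal-specific components.

The motivating analysis estimates the causal effect of maternal serum lipid
concentrations (HDL-C, LDL-C, triglycerides) on offspring birth weight (BW):
SNP–lipid associations come from one large GWAS (sample 1) and SNP–BW
associations from another (sample 2), the latter partitioned into maternal
(intrauterine) and fetal components so that estimates of the maternal causal
path are not confounded by the transmitted fetal genotype.

## What's inside

| module | contents |
| --- | --- |
| `duomr.summary_io` | GWAS summary-stat reading/writing (TSV, configurable column dialect, gzip), allele harmonization with palindrome handling, genome-wide / restricted ("one lipid only") instrument selection, positive-effect orientation |
| `duomr.partition` | closed-form partition of marginal own-BW / offspring-BW associations into maternal + fetal effects (transmission coefficient ½) with delta-method errors; duo-level conditional regression as its oracle |
| `duomr.estimators` | IVW, MR-Egger, weighted median, simple/weighted mode estimators with multiplicative random-effects SEs (floor 1) and parametric-bootstrap SEs for median/mode; leave-one-SNP-out reruns |
| `duomr.multivariable` | multivariable IVW (zero intercept) and multivariable Egger (per-exposure orientation, free intercept) across the three lipids jointly |
| `duomr.diagnostics` | I²GX (NOME check, both weightings), funnel-plot data with a numeric symmetry test, scatter-plot data with leave-one-out outlier flags, SD→grams conversion |
| `duomr.simulate` | mother–offspring duo simulator under the assumed causal diagram (Mendelian transmission, correlated lipids, optional balanced/directional/InSIDE-violating pleiotropy), GWAS-style summarisation, a fast summary-level generator, and named scenario presets |
| `duomr.pipeline`, `duomr.cli` | end-to-end orchestration (load → harmonize → select → orient → estimate → diagnose → report) with seeded determinism, skip accounting, provenance block and forest plots |

## CLI

```bash
# synthetic two-sample corpus (named presets; summary- or duo-level)
duomr simulate --preset paper-null --seed 1 --out corpus/

# full analysis grid: 5 univariate estimators x {unrestricted, restricted}
# x lipid, plus multivariable IVW/Egger, diagnostics and forest plots
duomr analyze \
  --sample1 hdl=corpus/sample1_hdl.tsv \
  --sample1 ldl=corpus/sample1_ldl.tsv \
  --sample1 tg=corpus/sample1_tg.tsv \
  --sample2 corpus/sample2.tsv \
  --seed 1 --out analysis/

# re-render an existing results directory
duomr report --results analysis/ --format forest-plot
```

`sample2.tsv` may be pre-partitioned (`beta_mat/se_mat/beta_fet/se_fet`) or
unpartitioned marginal pairs (`beta_own/se_own/beta_offspring/se_offspring`),
in which case the closed-form partition is applied first. Output:
`results.tsv` (long format incl. gram-scale columns), `diagnostics.tsv`,
`snp_usage.tsv`, `exclusions.log`, `provenance.txt`, `forest_<lipid>.png`.
Identical inputs + seed give byte-identical tables.

## Library use

```python
from duomr import (read_summary, harmonize, select_instruments, orient_positive,
                   SelectionRule, ivw, egger, weighted_median, mode_based)

exposures = {l: read_summary(f"sample1_{l}.tsv", trait=l) for l in ("hdl", "ldl", "tg")}
# outcome_mat / outcome_fet: lists of SummaryRecord with partitioned BW betas
table = harmonize(exposures, outcome_mat, outcome_fet)
sel = select_instruments(table, "ldl", SelectionRule(mode="restricted"))
oriented = orient_positive(sel, "ldl")
print(ivw(oriented), weighted_median(oriented, n_boot=1000, seed=1))
```

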