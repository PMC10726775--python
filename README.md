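# paindraw

Pixel-level analysis of body-map **pain drawings** — the pen-and-paper
sheets on which patients shade where it hurts.  The package digitizes
scanned template sheets into binary rasters, aggregates groups of
drawings into **pain profiles**, tests whether two groups (for example,
patients given a female vs a sex-neutral body outline) mark different
extents, and runs the exact-test battery for the accompanying
questionnaire data.  It is aimed at clinical researchers comparing pain
localization across cohorts, and ships a synthetic-data generator so the
whole pipeline is testable without patient data.

## The statistics at its core

**Ružička similarity.** For nonnegative vectors (rasters) `x`, `y`:

    RZI(x, y) = Σᵢ min(xᵢ, yᵢ) / Σᵢ max(xᵢ, yᵢ)  ∈ [0, 1]

On binary drawings this is the Jaccard index `|x∩y| / |x∪y|`; on pain
profiles (per-pixel marking proportions in `[0, 1]`) it is its weighted
generalization.  Only pixels marked somewhere contribute, so the measure
is not swamped by the empty background.

**Profile permutation test.** The observed statistic is the RZI between
the two groups' profiles ("origin similarity").  Group labels are
repeatedly reshuffled over the pooled drawings, preserving group sizes,
and the profile-level RZI is recomputed `B` times (default 1000).  The
default p-value is lower-tailed with add-one correction,
`p = (1 + #{RZI_b ≤ origin}) / (B + 1)`: under a real group difference
the true-label profiles are *less* similar than relabeled ones.  An
exhaustive enumeration over all label assignments is available for
small cohorts, plus an upper tail and a `paper_literal` mode
(`#{RZI_b > origin}/B`) found in existing field software.

**Questionnaire battery.** 2×2 response tables get Fisher's exact test
reported the way R's `fisher.test` reports it: a two-sided p-value by
the point-probability rule, the **conditional maximum-likelihood odds
ratio** under the noncentral hypergeometric law (solving `E_ψ[X] = x`),
and an exact 95% CI by inverting the one-sided tail tests at 2.5% per
side.  Wider tables get Pearson's chi-squared; age-style comparisons get
the two-sided Welch t-test.  Per-drawing marked-pixel counts are
compared on the log10 scale with a Wilcoxon rank-sum and a two-sample
t-test.

## Worked example

```python
from paindraw import fisher_exact_2x2, make_template, sample_cohort, \
    CohortConfig, permutation_test
from paindraw.datasets import load_questionnaire_counts

# bundled survey: "Do you consider the body outline sexless?"
table = load_questionnaire_counts()["q2_sexless"]
res = fisher_exact_2x2(table)
print(f"OR = {res.odds_ratio:.3f}, 95% CI ({res.ci_low:.3f}, "
      f"{res.ci_high:.3f}), p = {res.p_value:.3f}")

# synthetic two-group cohort at study scale: 24 sexless + 26 female sheets
tpl_n = make_template("sexless")
tpl_f = make_template("female")
group_n, group_f, _ = sample_cohort(tpl_n, tpl_f, CohortConfig(seed=0))
result = permutation_test(group_n, group_f, B=1000, tail="lower", seed=0)
print(f"origin RZI = {result.origin_rzi:.4f}, p = {result.p_value:.4f}")
```

prints

```
OR = 3.033, 95% CI (0.815, 12.151), p = 0.082
origin RZI = 0.0958, p = 0.7872
```

The odds ratio says patients with the sex-neutral outline judged it
"sexless" about 3× more often in odds terms, but the exact CI spans 1 —
no significant association at the 5% level.  The synthetic cohorts were
drawn with no built-in group effect, and the permutation test agrees:
the observed profile similarity (0.096) sits well inside the null
distribution (p = 0.79), so equal marking behaviour is not rejected.

A command-line surface wraps the same functions
(`paindraw simulate | ingest | pairwise | permtest | counts |
questionnaire | run`); `paindraw run --config run.yaml` executes the
whole pipeline into a run directory with profiles, histogram, heatmap,
boxplots, count reports and a seed-stamped manifest.

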