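# elderdep

Rule-based microsimulation of depression in old age, driven by
expert-elicited probability tables of social support.

## The problem

Late-life depression unfolds through an intertwined dynamic: key life events
(retirement, death of the spouse, moving, functional decline,
institutionalization, at mean ages 65, 70, 75, 80, 82) reshape an elderly
person's *social landscape* — the relative importance of five sources of
support (spouse, friends & children, professional caregiver, neighbors, and
loneliness as the absence of support) — and the contacts that landscape
produces in turn push mood up or down.  Long prospective cohorts that could
quantify this loop are rare, so the model quantifies it from expert opinion
instead: respondents fill in three column-stochastic tables,

* two 5×5 **Contact tables** `C` (sources × life stages, one for the
  non-depressive/neutral context, one for the depressive context), and
* one 3×5 **Impact table** `I` (impact sign × source),

each column summing to 100%.

## The model

Every person carries a depressive status `DS ∈ {+1, 0, −1}`
(non-depressive, neutral, depressive).  Once a year, at life stage `s`:

    source  ~  C_DS(· | s)          (depressive-context table iff DS = −1)
    impact  ~  I(· | source)        (values +1, 0, −1)
    DS      ←  clamp(DS + impact, −1, +1)

For a person frozen at one stage this is a three-state Markov chain with
transition kernel `P(d → clamp(d+i)) = Σ_src C_d(src|s) · I(i|src)`; the
package solves that chain exactly and uses it as an oracle for the sampler.

The individual process is embedded in a demographic loop: each year a
cohort of 1000 singles aged 61 enters (55.8% women; 16.3% of women and 9.7%
of men start depressive); 67.73% of the new women marry single men aged
62–63; permanent singles draw their remaining event ages
N((75, 80, 82), 2), order-enforced, and use a spouse-free Contact table; a
pre-computed number of individuals per age die to fit an empirical
mortality schedule, and each dead spouse leaves a widow who is depressive
for one bereavement year (skipping social contact) and whose remaining
events are rescheduled (usual ages if widowed at ≤ 70, else lags +5, +5, +2
years).  After 35 iterations the prevalence of `DS = −1` is read off by age
65–92 and averaged over 50 replicates.

Four scenario rule-sets: (1) the stand-alone individual process, (2) the
full marriage/widowhood demography, (3) plus an annual psychotherapy rule
(16.9% of the depressed recover, half to neutral, half to non-depressive),
(4) plus a permanent low socio-economic stratum (11.5%) whose Impact table
moves a quarter of the positive and neutral mass onto the negative impact.

Simulated mean curves are compared with a survey prevalence curve through
four indices: the number of ages inside the survey's 95% CI, the Wilcoxon
signed-rank p-value of the paired differences, the two-sample
Kolmogorov–Smirnov D against the survey's regression line, and the Pearson
correlation with that line.

## Worked example

Synthetic stand-ins for all three inputs (expert panel, mortality schedule,
survey curve) ship with the package, so the pipeline runs with no external
data:

```python
import numpy as np
from elderdep import (FixtureSpec, ScenarioConfig, TableSet, average_tables,
                      compute_mortality_schedule, gen_expert_panel, gen_mortality,
                      gen_empirical_curve, run_replicates, compare_curves)

spec = FixtureSpec(seed=1)                         # synthetic panel of 28 experts
panel = gen_expert_panel(spec)
nondep, dep, imp = average_tables(panel, "Type2")  # health-care professionals
tables = TableSet(nondep, dep, imp)
schedule = compute_mortality_schedule(gen_mortality(spec))

cfg = ScenarioConfig(scenario=3, n_replicates=10, seed=1)
summary = run_replicates(cfg, tables, schedule)

emp = gen_empirical_curve(spec)                    # synthetic survey curve with CIs
report = compare_curves(summary.mean, emp)
print("prevalence at 65/78/92:",
      np.round(summary.mean.prevalence[[0, 13, 27]], 3))
print("within CI:", report.occurrences_within_ci,
      " WSR p:", round(report.wsr_p, 4),
      " K-S D:", round(report.ks_D, 4),
      " r:", round(report.pearson_r, 4))
```

```
prevalence at 65/78/92: [0.24  0.288 0.319]
within CI: 7  WSR p: 0.0  K-S D: 0.8214  r: 0.8963
```

The simulated prevalence rises roughly linearly with age — the signature of
widowhood-driven depression spreading through the late-life span — and
correlates strongly with the survey trend line (r ≈ 0.90) while sitting at
a higher level (7 of 28 ages inside the CI): with random synthetic expert
tables the *shape* of the dynamic is reproduced, but the *level* depends on
the elicited opinions.

The same workflow is available from the shell:

```bash
elderdep fixtures --out-dir inputs --seed 1
elderdep tables --panel inputs/expert_tables.csv --profiles inputs/expert_profiles.csv \
         --typology Type2 --out-dir tables_out
elderdep simulate --scenario 3 --seed 1 --mortality inputs/mortality.csv --out-dir run3
elderdep compare --sim run3/mean_curve.csv --empirical inputs/empirical.csv --out-dir cmp3
```

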