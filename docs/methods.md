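# Methods

## Model

`elderdep` simulates the prevalence of depression among people aged 65–92
as the outcome of a yearly, individual-level stochastic process.  Each
person holds a three-state depressive status `DS` (+1 non-depressive, 0
neutral, −1 depressive; the neutral state keeps the dynamic chronic rather
than oscillatory), a gender, a marital status (single / married / widow), a
personal schedule of life-event ages, and two bookkeeping flags (first-year
widowhood; permanent low socio-economic status).

The behavioural core is a pair of column-stochastic 5×5 **Contact tables**
(sources of social support × life stages; one for the non-depressive and
neutral context, one for the depressive context) and a 3×5 **Impact table**
(impact sign × source), all stored in percent.  A year of life is: select
the stage column, draw a contact source, draw an impact in {+1, 0, −1} from
that source's column, add it to `DS` with clamping at ±1, age by one year.
Tables are kept in percent end to end and converted to probabilities only
inside the samplers, which avoids double-normalization; columns are
validated to sum to 100 (sums within 0.5 are silently renormalized as
questionnaire rounding, larger deviations renormalize with a warning;
negative cells and all-zero columns are rejected).

### Stage selection

The active Contact column is the column of the *most recently reached* life
event, defaulting to the retirement column before any event (the retirement
percentages apply even before the age of retirement, and the
institutionalization percentages until death).  Events a person never
experiences are simply absent from their schedule, which yields the right
behaviour for every marital situation: singles have no spouse-death event
(they skip column 2 and stay in the retirement column until they move), and
married people carry no post-widowhood events until an actual bereavement,
so they remain in the retirement column while the couple is intact.  The
boundary is inclusive: the event's column applies from the event year
itself.

### Derived tables

Two deterministic transforms of the elicited tables serve the scenarios:

* **spouse-free Contact table** (singles): the spousal row is zeroed and
  each column's remaining four cells are rescaled by `100/(100 − spouse)`;
  undefined when a column is 100% spousal.  Widows deliberately keep the
  *original* tables: respondents who attribute residual spousal importance
  after the death ("ghost contact") are thereby represented.
* **low-SES Impact table**: per column, a quarter of the positive and of
  the neutral mass is transferred onto the negative impact; mass is
  conserved exactly.

### Expert panels and typologies

A respondent record carries the three tables plus profile fields.  Two
orthogonal typologies classify respondents: by exposure (Type 1: no elderly
contact in the past week — this takes precedence; Type 2: contact and a
health-care occupation; Type 3: contact, other occupation) and by their
treatment of the dead spouse (Type A: strictly zero spousal importance in
all three post-widowhood stages of *both* Contact tables; Type B:
otherwise).  Aggregation is the cell-wise arithmetic mean over the selected
respondents (the mean of column-stochastic tables is column-stochastic, so
no renormalization follows); disagreement is summarised by the cell-wise
interquartile range, with quartiles by linear interpolation between order
statistics (the "type 7" convention — the common default, chosen because no
convention is otherwise dictated).

## Population loop

Each iteration represents one calendar year and performs, in order:
individual steps for everyone, injection of a fresh cohort of 1000 singles
aged 61, weddings, finalization of permanent singles' schedules, mortality
with the widowhood cascade, and (when the rule is active) treatment.
Treatment runs last so that a widow bereaved this year is not treated
within her bereavement year; the ordering of the earlier steps follows the
demographic logic (new women must exist before weddings; deaths must see
the post-wedding state).

* **Cohorts.** Gender is woman with probability 0.558.  Initial `DS` is
  −1 with probability 0.163 (women) / 0.097 (men), otherwise 0 or +1 with
  equal probability.  Retirement age is N(65, 2).
* **Weddings.** Each year, 67.73% of the newly injected 61-year-old women
  (rounded, with the fractional remainder carried across years so the
  long-run share is exact) marry single men aged 62–63, drawn uniformly
  without replacement from the pooled two age bins — at steady state the
  bins are near-equal, so husband ages split about evenly.  Links are
  symmetric.  In the first years no such men exist and as many marriages as
  possible are made (logged).  After 63 the unmarried stay single for life.
* **Schedules.** Permanent singles draw moving / functional decline /
  institutionalization ages N((75, 80, 82), 2).  Draws are order-enforced:
  scanning the canonical sequence, an event drawn at or before its
  predecessor is reset to predecessor + 1.
* **Mortality.** Removal counts per age 66–92 are pre-computed from a
  mortality-rate schedule applied to a virtual cohort of 1000 at 65:
  counts are successive differences of the rounded cumulative real-valued
  death curve, so rounding never drifts; every survivor is removed at 93.
  Each year exactly the scheduled number is removed uniformly at random
  per age bin (an underfilled pre-burn-in bin is emptied, with a warning).
* **Widowhood cascade.** A removed married person's survivor turns widow:
  `DS = −1`, the first-year flag is raised (next year the widow skips
  social contact, stays depressive and merely ages), and the remaining
  events are rescheduled — usual mean ages (75, 80, 82) if widowed at or
  before 70, otherwise widowhood age +5, +10, +12 (cumulative lags +5, +5,
  +2).
* **Treatment** (scenario 3): every depressed individual is independently
  selected with probability 0.169 each year (a per-individual Bernoulli
  reading of "selected each year"); the selected recover to 0 or +1 with
  equal probability.
* **Low SES** (scenario 4): a permanent flag assigned at cohort creation
  with probability 0.115; flagged individuals sample impacts from the
  SES-adjusted Impact table.  Contact tables are unchanged.

Scenario 1 bypasses the demography: everyone is notionally married (no
partner agent, no bereavement year), starts neutral, and carries a full
five-event schedule including a spouse-death age N(70, 2).  Scenario
combinations (e.g. treatment + SES) are available by explicit flags on the
configuration.

After 35 iterations — enough for every reporting age 65–92 to be populated
by fully simulated individuals, including the marriage burn-in — the
prevalence of `DS = −1` per age is computed over the living population, and
50 replicates (replicate *r* reseeded with `seed + r`) are averaged.

## Comparison battery

Against an empirical curve with 95% CIs on the same 28-age grid the package
reports: the count of ages with the simulated value inside the CI (bounds
inclusive); the two-sided Wilcoxon signed-rank p-value (zero differences
discarded; exact null for ≤ 25 informative pairs without ties, otherwise a
normal approximation with tie correction; all-zero differences give p = 1
with a warning); the OLS regression of the empirical curve on age; the
two-sample Kolmogorov–Smirnov D between the simulated values and the
regression line (with 28-point samples D is a multiple of 1/28 — D, not its
p-value, is the headline index); and the Pearson correlation with that
line.  The standard statistics are delegated to scipy.stats; the test-suite
checks them against independent brute-force oracles (sign-assignment
enumeration, a naive ECDF scan, the normal equations, the covariance
formula).

## Synthetic inputs

The fixtures module generates all three inputs deterministically from a
seed:

* **Expert panel** (default 28 respondents): every table column is a
  symmetric Dirichlet draw (concentration 2.0 — informative but
  non-degenerate columns) scaled to percent; 18/28 of respondents are
  constructed Type A by zeroing the spousal row in the post-widowhood
  columns; profiles guarantee all three contact typologies occur.
* **Mortality**: `rate(age) = min(1, 0.013 · e^{0.09 (age−65)})`, about
  1.4% at 66 rising to 15% at 92 — a realistic elderly schedule.
* **Survey curve**: a linear trend from about 12% at 65 to 25% at 92,
  observed as binomial proportions at 200 respondents per age with Wald
  95% intervals (ages with fewer than 50 respondents would be excluded in
  a real survey, so smaller sizes are rejected).

What passing tests on these fixtures show — and do not show.  They verify
the machinery: parameter recovery, conservation, the Markov oracle, the
direction of the scenario effects.  They do not certify agreement with any
real survey: the *level* of simulated prevalence depends on the elicited
tables, and symmetric Dirichlet columns make the mean Impact table
⅓/⅓/⅓, which yields a higher depressive baseline (≈ 0.40 under scenario 2)
than real expert opinion, whose impact columns lean positive.  One
consequence is structural: with these fixtures the treatment rule shifts
curves down by an order more than the SES rule shifts them up, so the
near-cancellation of the two combined rules that holds under elicited
tables does not hold under the synthetic ones.  Loaders ingest transcribed
real inputs (same CSV layouts) whenever they are available.

## Numerical choices and reproducibility

* One seeded NumPy generator per replicate; draws are consumed in a fixed
  order (contact, then impact), making runs bit-reproducible for a given
  configuration and seed.
* Inverse-CDF sampling over cumulative percent columns, cached per table
  set.
* The Markov-oracle tests compare long-run simulated depressive fractions
  with the stationary distribution from an independent linear solve; the
  Monte-Carlo standard error uses the chain's exact asymptotic variance
  (Poisson equation), since the yearly indicator is autocorrelated and an
  iid binomial error would be anti-conservative.
* Degenerate inputs fail loudly: all-zero table columns, 100%-spousal
  columns reaching a single, stepping a dead person, mismatched age grids,
  zero-variance correlations.
* Problem sizes in the test-suite: full study conditions (1000 × 35 × 50)
  for the scenario-ordering and pipeline checks; reduced cohorts with a
  mortality schedule re-based to the cohort size for unit-level runs.

## Known limitations

Mortality is unisex and independent of depressive status; no remarriage,
no cohort effects, no within-year multiplicity of contacts; the treatment
rule is a Bernoulli selection rather than an exact annual quota; marriage
is decided at 61 rather than observed at 65.  These mirror the scope of
the underlying rule set rather than accidents of implementation.
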