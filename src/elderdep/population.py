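"""Population loop: cohorts, marriage, mortality, widowhood, scenarios.

Each simulated year a new cohort of 61-year-olds enters, every individual is
advanced one year by the agents module, new 61-year-old women are wed to
single men aged 62-63, permanent singles get their remaining event ages,
a pre-computed number of individuals per age die (their spouses turning
widow, depressive, with a first-year bereavement flag), and — in the
treatment scenario — a fraction of the depressed recover.  After 35 years
the prevalence of the depressive state is read off the final population by
age 65-92.

Four scenario rule-sets are supported:

1. a stand-alone individual process (everyone is notionally married and
   transitions through all five life stages on a personal schedule; no
   partner agents, no forced bereavement year);
2. a gendered population with real marriage, widowhood cascade and the
   one-year bereavement rule;
3. scenario 2 plus an annual psychotherapy rule (16.9% of the depressed
   recover, half to neutral, half to non-depressive);
4. scenario 2 plus a permanent low socio-economic stratum (11.5%) whose
   Impact table shifts a quarter of positive and neutral mass to negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .agents import (
    MAN,
    MARRIED,
    SINGLE,
    WIDOW,
    WOMAN,
    AgePath,
    Person,
    TableSet,
    step_individual,
)

logger = logging.getLogger(__name__)

AGE_GRID = np.arange(65, 93)  # the 28 reporting ages


@dataclass
class ScenarioConfig:
    """All scalar parameters of a run.

    Defaults are the study conditions: cohorts of 1000 at age 61, 35 yearly
    iterations, 50 replicates, event ages N((65,70,75,80,82), sd 2), 55.8%
    women, initial depression 16.3% (women) / 9.7% (men), 67.73% of women
    married, 16.9% of the depressed treated yearly (scenario 3), 11.5%
    low-SES (scenario 4), everyone removed at age 93.
    """

    scenario: int = 2
    cohort_size: int = 1000
    n_iterations: int = 35
    n_replicates: int = 50
    mean_event_ages: tuple[float, ...] = (65.0, 70.0, 75.0, 80.0, 82.0)
    event_age_sd: float = 2.0
    post_widowhood_lags: tuple[float, ...] = (5.0, 5.0, 2.0)
    prop_women: float = 0.558
    init_depressed_women: float = 0.163
    init_depressed_men: float = 0.097
    prop_married_women: float = 0.6773
    treatment_fraction: float = 0.169
    low_ses_fraction: float = 0.115
    terminal_age: int = 93
    seed: int = 0
    # None -> the scenario's default; set to combine rules (e.g. 3+4)
    enable_treatment: bool | None = None
    enable_ses: bool | None = None

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3, 4):
            raise ValueError(f"scenario must be 1-4, got {self.scenario}")
        for name in (
            "prop_women",
            "init_depressed_women",
            "init_depressed_men",
            "prop_married_women",
            "treatment_fraction",
            "low_ses_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if list(self.mean_event_ages) != sorted(self.mean_event_ages):
            raise ValueError("mean_event_ages must be increasing")
        if self.cohort_size < 1 or self.n_iterations < 1 or self.n_replicates < 1:
            raise ValueError("cohort_size, n_iterations, n_replicates must be >= 1")

    @property
    def uses_marriage(self) -> bool:
        return self.scenario >= 2

    @property
    def treatment_on(self) -> bool:
        if self.enable_treatment is not None:
            return self.enable_treatment
        return self.scenario == 3

    @property
    def ses_on(self) -> bool:
        if self.enable_ses is not None:
            return self.enable_ses
        return self.scenario == 4


@dataclass(frozen=True)
class MortalitySchedule:
    """Fixed per-age removal counts fitted to mortality rates.

    Counts are pre-computed on a virtual cohort of ``base`` individuals at
    age 65; every survivor is removed at ``terminal_age``.
    """

    ages: np.ndarray  # 66..92
    removals: np.ndarray  # same length, integer counts
    base: int = 1000
    terminal_age: int = 93

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.removals):
            raise ValueError("ages and removals must align")
        if np.any(self.removals < 0):
            raise ValueError("negative removal count")
        surv = self.base
        for a, k in zip(self.ages, self.removals):
            if k > surv:
                raise ValueError(f"removals at age {a} exceed survivors ({k} > {surv})")
            surv -= k

    @property
    def terminal_removals(self) -> int:
        return self.base - int(self.removals.sum())

    def removals_at(self, age: int) -> int:
        idx = np.where(self.ages == age)[0]
        return int(self.removals[idx[0]]) if idx.size else 0


@dataclass
class PrevalenceCurve:
    """Prevalence of DS = -1 among the living, by age.

    Empirical curves additionally carry 95% confidence bounds.  Ages must be
    contiguous; bins that hold no living individuals (only possible in
    truncated test runs) are NaN.
    """

    ages: np.ndarray
    prevalence: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.prevalence = np.asarray(self.prevalence, dtype=float)
        if self.ages.shape != self.prevalence.shape:
            raise ValueError("ages and prevalence must align")
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("ages must be contiguous")
        finite = self.prevalence[np.isfinite(self.prevalence)]
        if np.any((finite < 0) | (finite > 1)):
            raise ValueError("prevalence outside [0, 1]")
        for name in ("ci_low", "ci_high"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.ages.shape:
                    raise ValueError(f"{name} must align with ages")
                setattr(self, name, v)

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None and self.ci_high is not None

    def to_frame(self) -> pd.DataFrame:
        data = {"age": self.ages, "prevalence": self.prevalence}
        if self.has_ci:
            data["ci_low"] = self.ci_low
            data["ci_high"] = self.ci_high
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, require_ci: bool = False) -> "PrevalenceCurve":
        df = pd.read_csv(path)
        cols = set(df.columns)
        mean_col = "prevalence" if "prevalence" in cols else "mean"
        if "age" not in cols or mean_col not in cols:
            raise ValueError(f"curve CSV needs columns age and prevalence/mean, has {sorted(cols)}")
        if require_ci and not {"ci_low", "ci_high"}.issubset(cols):
            raise ValueError("curve CSV is missing ci_low/ci_high columns")
        df = df.sort_values("age")
        return cls(
            ages=df["age"].to_numpy(),
            prevalence=df[mean_col].to_numpy(),
            ci_low=df["ci_low"].to_numpy() if "ci_low" in cols else None,
            ci_high=df["ci_high"].to_numpy() if "ci_high" in cols else None,
        )


@dataclass
class SimulationResult:
    """One replicate: final prevalence curve plus run diagnostics."""

    curve: PrevalenceCurve
    population: list[Person]
    injected: int
    deaths: int
    treated: int
    treatment_eligible: int
    annual_treated_fraction: list[float] = field(default_factory=list)


@dataclass
class ReplicateSummary:
    """Mean curve over replicates, per-replicate curves, optional statistics."""

    mean: PrevalenceCurve
    curves: list[PrevalenceCurve]
    stats: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# cohort creation and event scheduling
# ---------------------------------------------------------------------------


def enforce_event_order(ages: Sequence[float]) -> list[float]:
    """Force strictly increasing event ages with a one-year minimum lag.

    Scanning the canonical event sequence, any event drawn at or before its
    predecessor is reset to predecessor + 1.
    """
    out = list(ages)
    for i in range(1, len(out)):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + 1.0
    return out


def generate_age_path(
    marital: str,
    retirement_age: float,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    full: bool = False,
) -> AgePath:
    """Draw the remaining event ages for one person.

    ``full`` draws all five events (scenario 1's stand-alone individuals,
    spouse death included); otherwise singles get moving, functional decline
    and institutionalization only.  Draws are normal around the mean event
    ages with sd ``event_age_sd`` and order-enforced.
    """
    m = cfg.mean_event_ages
    sd = cfg.event_age_sd
    if full:
        drawn = [retirement_age] + [rng.normal(mu, sd) for mu in m[1:]]
        ret, widow, move, decline, inst = enforce_event_order(drawn)
        return AgePath(ret, widow, move, decline, inst)
    if marital != SINGLE:
        raise ValueError(
            "generate_age_path only finalizes singles; widows are rescheduled "
            "by reschedule_after_widowhood"
        )
    drawn = [retirement_age] + [rng.normal(mu, sd) for mu in m[2:]]
    ret, move, decline, inst = enforce_event_order(drawn)
    return AgePath(ret, None, move, decline, inst)


def reschedule_after_widowhood(
    path: AgePath, widowhood_age: float, cfg: ScenarioConfig
) -> AgePath:
    """Set the three post-widowhood event ages on a new widow's path.

    Widowhood at or before 70 preserves the usual mean ages (75, 80, 82);
    later widowhood scatters the remaining events at the post-widowhood lags
    (+5, +5, +2 years cumulatively) till the end of life.
    """
    path.spouse_death = float(widowhood_age)
    if widowhood_age <= cfg.mean_event_ages[1]:
        path.moving, path.functional_decline, path.institutionalization = (
            cfg.mean_event_ages[2],
            cfg.mean_event_ages[3],
            cfg.mean_event_ages[4],
        )
    else:
        lags = np.cumsum(cfg.post_widowhood_lags)
        path.moving = widowhood_age + lags[0]
        path.functional_decline = widowhood_age + lags[1]
        path.institutionalization = widowhood_age + lags[2]
    return path


def init_cohort(
    cfg: ScenarioConfig, rng: np.random.Generator, start_id: int = 0
) -> list[Person]:
    """Create a cohort of 61-year-old singles.

    Gender is woman with probability 55.8%; initial DS is depressive for
    16.3% of women and 9.7% of men, otherwise neutral or non-depressive with
    equal probability; retirement age is N(65, sd).  Scenario 1 instead
    starts everyone neutral with a full five-event personal schedule and a
    notional spouse.  Scenario 4 (or any run with the SES rule on) flags
    individuals low-SES for life with probability 11.5%.
    """
    n = cfg.cohort_size
    women = rng.random(n) < cfg.prop_women
    retirement = rng.normal(cfg.mean_event_ages[0], cfg.event_age_sd, n)
    cohort: list[Person] = []
    if not cfg.uses_marriage:
        for i in range(n):
            path = generate_age_path(MARRIED, retirement[i], cfg, rng, full=True)
            p = Person(
                person_id=start_id + i,
                age=61,
                gender=WOMAN if women[i] else MAN,
                ds=0,
                marital_status=MARRIED,
                age_path=path,
            )
            p.path_finalized = True
            cohort.append(p)
        return cohort
    u_dep = rng.random(n)
    u_split = rng.random(n)
    ses = rng.random(n) < cfg.low_ses_fraction if cfg.ses_on else np.zeros(n, bool)
    for i in range(n):
        p_dep = cfg.init_depressed_women if women[i] else cfg.init_depressed_men
        if u_dep[i] < p_dep:
            ds = -1
        else:
            ds = 0 if u_split[i] < 0.5 else 1
        cohort.append(
            Person(
                person_id=start_id + i,
                age=61,
                gender=WOMAN if women[i] else MAN,
                ds=ds,
                marital_status=SINGLE,
                age_path=AgePath(retirement[i]),
                low_ses=bool(ses[i]),
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# marriage
# ---------------------------------------------------------------------------


def wed_cohort(
    population: list[Person],
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    carry: float = 0.0,
) -> float:
    """Marry 67.73% of the new 61-year-old women to single men aged 62-63.

    The target count is round(fraction x women) with the fractional
    remainder carried across iterations so the long-run married share hits
    the configured fraction exactly.  Husbands are drawn uniformly without
    replacement from the pooled single men aged 62 and 63.  A shortage of
    men (the first iterations) marries as many as possible and logs a
    warning.  Returns the updated carry.
    """
    women = [
        p
        for p in population
        if p.alive and p.age == 61 and p.gender == WOMAN and p.marital_status == SINGLE
    ]
    men = [
        p
        for p in population
        if p.alive
        and p.age in (62, 63)
        and p.gender == MAN
        and p.marital_status == SINGLE
    ]
    target = cfg.prop_married_women * len(women) + carry
    k = int(np.floor(target + 0.5))
    carry = target - k
    if k > min(len(women), len(men)):
        short = min(len(women), len(men))
        logger.warning(
            "wanted %d marriages but only %d possible (%d women, %d men)",
            k,
            short,
            len(women),
            len(men),
        )
        k = short
    if k == 0:
        return carry
    brides = [women[i] for i in rng.choice(len(women), size=k, replace=False)]
    grooms = [men[i] for i in rng.choice(len(men), size=k, replace=False)]
    for w, m in zip(brides, grooms):
        w.marital_status = MARRIED
        m.marital_status = MARRIED
        w.spouse = m
        m.spouse = w
    return carry


def finalize_single_paths(
    population: list[Person], cfg: ScenarioConfig, rng: np.random.Generator
) -> None:
    """Draw moving/decline/institutionalization ages for permanent singles.

    After 63 the unmarried stay single for life, so their remaining event
    ages can be generated (singles never experience widowhood).
    """
    for p in population:
        if (
            p.alive
            and p.marital_status == SINGLE
            and p.age >= 64
            and not p.path_finalized
        ):
            p.age_path = generate_age_path(SINGLE, p.age_path.retirement, cfg, rng)
            p.path_finalized = True


# ---------------------------------------------------------------------------
# mortality and the widowhood cascade
# ---------------------------------------------------------------------------


def compute_mortality_schedule(
    rates, base: int = 1000, terminal_age: int = 93
) -> MortalitySchedule:
    """Integer removal counts per age fitted to per-age mortality rates.

    ``rates`` maps age -> mortality fraction (mapping, pandas Series, or a
    DataFrame with columns age/rate), ages 66..terminal_age-1.  Counts are
    the successive differences of the rounded cumulative real-valued death
    curve of a virtual cohort of ``base`` at 65, so rounding errors never
    accumulate; all survivors are removed at the terminal age.
    """
    if isinstance(rates, pd.DataFrame):
        if not {"age", "rate"}.issubset(rates.columns):
            raise ValueError("mortality DataFrame needs columns age, rate")
        rates = dict(zip(rates["age"].astype(int), rates["rate"].astype(float)))
    elif isinstance(rates, pd.Series):
        rates = {int(a): float(r) for a, r in rates.items()}
    ages = np.arange(66, terminal_age)
    missing = [int(a) for a in ages if a not in rates]
    if missing:
        raise ValueError(f"mortality rates missing for ages {missing}")
    removals = []
    surv_real = float(base)
    cum = 0.0
    removed = 0
    for a in ages:
        r = float(rates[int(a)])
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"mortality rate at age {a} outside [0,1]: {r}")
        cum += surv_real * r
        surv_real -= surv_real * r
        k = int(np.floor(cum + 0.5)) - removed
        k = max(0, min(k, base - removed))
        removals.append(k)
        removed += k
    return MortalitySchedule(
        ages=ages,
        removals=np.asarray(removals, dtype=int),
        base=base,
        terminal_age=terminal_age,
    )


def _make_widow(survivor: Person, cfg: ScenarioConfig) -> None:
    """The widowhood cascade on the surviving spouse."""
    survivor.marital_status = WIDOW
    survivor.spouse = None
    survivor.ds = -1
    survivor.historic = 1
    reschedule_after_widowhood(survivor.age_path, survivor.age, cfg)
    survivor.path_finalized = True


def apply_mortality(
    population: list[Person],
    schedule: MortalitySchedule,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[list[Person], int]:
    """Remove the scheduled number of individuals per age, cascade widowhood.

    Per age 66..92 exactly the scheduled count is removed uniformly at
    random from that age bin (all of an underfilled pre-burn-in bin, with a
    warning); everyone at or past the terminal age is removed.  In scenarios
    with marriage, each removed married person's spouse turns widow: DS is
    set to -1 for the bereavement year, the historic flag raised, and the
    remaining life events rescheduled from the widowhood age.  Returns the
    surviving population and the number of deaths.
    """
    bins: dict[int, list[Person]] = {}
    terminal: list[Person] = []
    for p in population:
        if not p.alive:
            continue
        if p.age >= cfg.terminal_age:
            terminal.append(p)
        else:
            bins.setdefault(p.age, []).append(p)
    doomed: list[Person] = list(terminal)
    for age, k in zip(schedule.ages, schedule.removals):
        if k == 0:
            continue
        group = bins.get(int(age), [])
        if len(group) < k:
            if group:
                logger.warning(
                    "age %d holds %d individuals, %d removals scheduled; "
                    "removing all (pre-burn-in)",
                    age,
                    len(group),
                    k,
                )
            doomed.extend(group)
        else:
            idx = rng.choice(len(group), size=k, replace=False)
            doomed.extend(group[i] for i in idx)
    deaths = 0
    for p in doomed:
        if not p.alive:
            continue
        p.alive = False
        deaths += 1
        if cfg.uses_marriage and p.marital_status == MARRIED and p.spouse is not None:
            survivor = p.spouse
            p.spouse = None
            if survivor.alive:
                _make_widow(survivor, cfg)
    return [p for p in population if p.alive], deaths


# ---------------------------------------------------------------------------
# treatment
# ---------------------------------------------------------------------------


def apply_treatment(
    population: list[Person], cfg: ScenarioConfig, rng: np.random.Generator
) -> tuple[list[Person], int, int]:
    """Yearly psychotherapy rule: each depressed individual is selected
    independently with probability ``treatment_fraction``; the selected
    recover to neutral (half) or non-depressive (half).

    Returns (population, number selected, number eligible).
    """
    selected = 0
    eligible = 0
    for p in population:
        if p.alive and p.ds == -1:
            eligible += 1
            if rng.random() < cfg.treatment_fraction:
                selected += 1
                p.ds = 0 if rng.random() < 0.5 else 1
    return population, selected, eligible


# ---------------------------------------------------------------------------
# the simulation proper
# ---------------------------------------------------------------------------


def prevalence_curve(population: Sequence[Person], ages: np.ndarray = AGE_GRID) -> PrevalenceCurve:
    """Fraction of living individuals with DS = -1 at each reporting age."""
    alive_count = {int(a): 0 for a in ages}
    dep_count = {int(a): 0 for a in ages}
    for p in population:
        if p.alive and p.age in alive_count:
            alive_count[p.age] += 1
            if p.ds == -1:
                dep_count[p.age] += 1
    prev = np.array(
        [
            dep_count[int(a)] / alive_count[int(a)] if alive_count[int(a)] else np.nan
            for a in ages
        ]
    )
    return PrevalenceCurve(ages=ages.copy(), prevalence=prev)


def run_simulation(
    cfg: ScenarioConfig,
    tables: TableSet,
    schedule: MortalitySchedule,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """One replicate of the population loop.

    Per iteration: step every individual, inject a fresh 61-year-old cohort,
    wed (scenarios >= 2), finalize permanent singles' event ages, apply
    mortality with the widowhood cascade, then treatment (if the rule is
    on).  Treatment runs last so a newly bereaved widow is not treated
    within her bereavement year.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    population: list[Person] = []
    next_id = 0
    carry = 0.0
    injected = deaths = treated = eligible = 0
    annual_fracs: list[float] = []
    for _ in range(cfg.n_iterations):
        for p in population:
            step_individual(p, tables, rng)
        cohort = init_cohort(cfg, rng, start_id=next_id)
        next_id += len(cohort)
        injected += len(cohort)
        population.extend(cohort)
        if cfg.uses_marriage:
            carry = wed_cohort(population, cfg, rng, carry)
            finalize_single_paths(population, cfg, rng)
        population, d = apply_mortality(population, schedule, cfg, rng)
        deaths += d
        if cfg.treatment_on:
            population, sel, elig = apply_treatment(population, cfg, rng)
            treated += sel
            eligible += elig
            if elig:
                annual_fracs.append(sel / elig)
    return SimulationResult(
        curve=prevalence_curve(population),
        population=population,
        injected=injected,
        deaths=deaths,
        treated=treated,
        treatment_eligible=eligible,
        annual_treated_fraction=annual_fracs,
    )


def run_replicates(
    cfg: ScenarioConfig,
    tables: TableSet,
    schedule: MortalitySchedule,
    stat_fns: Mapping[str, Callable[[SimulationResult], float]] | None = None,
) -> ReplicateSummary:
    """Run ``cfg.n_replicates`` independent replicates and average.

    Replicate r uses seed ``cfg.seed + r``.  ``stat_fns`` maps a name to a
    function of the per-replicate :class:`SimulationResult`; the returned
    summary then carries a replicate x statistic DataFrame (final
    populations themselves are not retained).
    """
    curves: list[PrevalenceCurve] = []
    rows = []
    for r in range(cfg.n_replicates):
        rng = np.random.default_rng(cfg.seed + r)
        res = run_simulation(cfg, tables, schedule, rng)
        curves.append(res.curve)
        if stat_fns:
            rows.append({name: fn(res) for name, fn in stat_fns.items()})
    stacked = np.vstack([c.prevalence for c in curves])
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN age bins
        mean_prev = np.nanmean(stacked, axis=0)
    mean = PrevalenceCurve(ages=curves[0].ages.copy(), prevalence=mean_prev)
    stats = pd.DataFrame(rows) if stat_fns else None
    return ReplicateSummary(mean=mean, curves=curves, stats=stats)


def write_replicates_csv(summary: ReplicateSummary, path) -> None:
    """Per-replicate and mean curves in long form (age, prevalence, replicate)."""
    frames = []
    for r, c in enumerate(summary.curves):
        df = c.to_frame()
        df["replicate"] = r
        frames.append(df)
    mean_df = summary.mean.to_frame()
    mean_df["replicate"] = "mean"
    frames.append(mean_df)
    pd.concat(frames).to_csv(path, index=False, float_format="%.17g")
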