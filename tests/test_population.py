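"""Population loop: cohorts, marriage, mortality, widowhood, scenarios."""

import numpy as np
import pytest

from elderdep.agents import AgePath, Person, TableSet
from elderdep.population import (
    AGE_GRID,
    MortalitySchedule,
    PrevalenceCurve,
    ScenarioConfig,
    apply_mortality,
    apply_treatment,
    compute_mortality_schedule,
    enforce_event_order,
    generate_age_path,
    init_cohort,
    prevalence_curve,
    reschedule_after_widowhood,
    run_replicates,
    run_simulation,
    wed_cohort,
)
from elderdep.tables import validate_table


def degenerate_impact_set(row_idx, seed=0):
    """TableSet with random contacts but a deterministic impact sign."""
    rng = np.random.default_rng(seed)
    g = np.zeros((3, 5))
    g[row_idx, :] = 100.0
    return TableSet(
        validate_table(rng.random((5, 5)) + 0.05, "contact"),
        validate_table(rng.random((5, 5)) + 0.05, "contact", mood_context="depressive"),
        validate_table(g, "impact"),
    )


class TestEventOrder:
    @pytest.mark.parametrize(
        "drawn, expected",
        [
            ([65, 74, 72, 80, 82], [65, 74, 75, 80, 82]),
            ([65, 70, 75, 80, 82], [65, 70, 75, 80, 82]),
            ([65, 74, 74, 74, 82], [65, 74, 75, 76, 82]),
        ],
    )
    def test_late_events_pushed_one_year_past_predecessor(self, drawn, expected):
        assert enforce_event_order(drawn) == expected

    def test_zero_noise_gives_exact_mean_ages_for_singles(self, rng):
        cfg = ScenarioConfig(scenario=2, event_age_sd=0.0)
        path = generate_age_path("single", 65.0, cfg, rng)
        assert (path.moving, path.functional_decline, path.institutionalization) == (
            75.0,
            80.0,
            82.0,
        )
        assert path.spouse_death is None

    def test_single_paths_are_increasing_without_widowhood(self, rng):
        cfg = ScenarioConfig(scenario=2)
        for _ in range(200):
            p = generate_age_path("single", 65.0, cfg, rng)
            ages = [p.retirement, p.moving, p.functional_decline, p.institutionalization]
            assert all(b > a for a, b in zip(ages, ages[1:]))
            assert p.spouse_death is None

    def test_mean_moving_age_recovers_its_parameter(self, rng):
        cfg = ScenarioConfig(scenario=2)
        draws = [generate_age_path("single", 65.0, cfg, rng).moving for _ in range(10_000)]
        se = cfg.event_age_sd / np.sqrt(len(draws))
        # order enforcement acts only in the rare retirement>moving tail
        assert abs(np.mean(draws) - 75.0) < 3 * se + 0.05


class TestRescheduleAfterWidowhood:
    @pytest.mark.parametrize(
        "w, expected",
        [(68, (75.0, 80.0, 82.0)), (70, (75.0, 80.0, 82.0)), (78, (83.0, 88.0, 90.0))],
    )
    def test_early_widowhood_keeps_usual_ages_late_uses_lags(self, w, expected):
        cfg = ScenarioConfig(scenario=2)
        path = reschedule_after_widowhood(AgePath(65.0), w, cfg)
        assert (path.moving, path.functional_decline, path.institutionalization) == expected
        assert path.spouse_death == w


class TestMortalitySchedule:
    def test_zero_rates_defer_all_deaths_to_terminal_age(self):
        sched = compute_mortality_schedule({a: 0.0 for a in range(66, 93)})
        assert sched.removals.sum() == 0
        assert sched.terminal_removals == 1000

    def test_constant_rate_yields_geometric_decay_counts(self):
        sched = compute_mortality_schedule({a: 0.1 for a in range(66, 93)})
        assert list(sched.removals[:3]) == [100, 90, 81]

    def test_removals_conserve_the_virtual_cohort(self, fixture_spec):
        from elderdep.fixtures import gen_mortality

        sched = compute_mortality_schedule(gen_mortality(fixture_spec))
        assert sched.removals.sum() + sched.terminal_removals == 1000

    def test_rate_outside_unit_interval_errors(self):
        rates = {a: 0.1 for a in range(66, 93)}
        rates[70] = 1.5
        with pytest.raises(ValueError, match="outside"):
            compute_mortality_schedule(rates)

    def test_missing_age_errors(self):
        with pytest.raises(ValueError, match="missing"):
            compute_mortality_schedule({a: 0.1 for a in range(66, 92)})  # 92 absent


class TestInitCohort:
    def test_scenario1_cohort_is_neutral_with_full_paths(self, rng):
        cfg = ScenarioConfig(scenario=1, cohort_size=500)
        cohort = init_cohort(cfg, rng)
        assert all(p.ds == 0 for p in cohort)
        assert all(p.age_path.spouse_death is not None for p in cohort)
        assert all(p.age == 61 for p in cohort)

    def test_scenario2_proportions_recover_parameters(self, rng):
        cfg = ScenarioConfig(scenario=2, cohort_size=100_000)
        cohort = init_cohort(cfg, rng)
        n = len(cohort)
        women = [p for p in cohort if p.gender == "woman"]
        frac_women = len(women) / n
        se = np.sqrt(0.558 * 0.442 / n)
        assert abs(frac_women - 0.558) < 3 * se
        dep_women = np.mean([p.ds == -1 for p in women])
        se = np.sqrt(0.163 * 0.837 / len(women))
        assert abs(dep_women - 0.163) < 3 * se
        men = [p for p in cohort if p.gender == "man"]
        dep_men = np.mean([p.ds == -1 for p in men])
        se = np.sqrt(0.097 * 0.903 / len(men))
        assert abs(dep_men - 0.097) < 3 * se

    def test_non_depressed_split_neutral_vs_positive_is_even(self, rng):
        cfg = ScenarioConfig(scenario=2, cohort_size=100_000)
        cohort = init_cohort(cfg, rng)
        nd = [p.ds for p in cohort if p.ds != -1]
        frac_neutral = np.mean([d == 0 for d in nd])
        se = np.sqrt(0.25 / len(nd))
        assert abs(frac_neutral - 0.5) < 3 * se

    def test_ses_flag_only_set_when_rule_active(self, rng):
        cfg = ScenarioConfig(scenario=2, cohort_size=2000)
        assert not any(p.low_ses for p in init_cohort(cfg, rng))
        cfg4 = ScenarioConfig(scenario=4, cohort_size=50_000)
        frac = np.mean([p.low_ses for p in init_cohort(cfg4, rng)])
        se = np.sqrt(0.115 * 0.885 / 50_000)
        assert abs(frac - 0.115) < 3 * se


class TestWedding:
    def test_no_available_men_means_no_marriages(self, rng, caplog):
        cfg = ScenarioConfig(scenario=2, cohort_size=200)
        pop = init_cohort(cfg, rng)
        wed_cohort(pop, cfg, rng)
        assert not any(p.marital_status == "married" for p in pop)

    def test_married_pairs_link_symmetrically(self, rng):
        cfg = ScenarioConfig(scenario=2, cohort_size=400)
        pop = init_cohort(cfg, rng)
        for p in pop:  # make two older male cohorts available
            if p.gender == "man":
                p.age = 62 if p.person_id % 2 else 63
        women61 = init_cohort(cfg, rng, start_id=1000)
        pop.extend(women61)
        wed_cohort(pop, cfg, rng)
        married = [p for p in pop if p.marital_status == "married"]
        assert married, "some marriages expected"
        for p in married:
            assert p.spouse is not None and p.spouse.spouse is p

    def test_long_run_married_fraction_matches_parameter(self, table_set, schedule):
        cfg = ScenarioConfig(scenario=2, cohort_size=1000, n_iterations=8, seed=3)
        res = run_simulation(cfg, table_set, schedule)
        women = [
            p for p in res.population if p.gender == "woman" and 62 <= p.age <= 64
        ]
        frac = np.mean([p.marital_status == "married" for p in women])
        se = np.sqrt(0.6773 * 0.3227 / len(women))
        assert abs(frac - 0.6773) < 3 * se + 1 / len(women)


class TestMortalityApplication:
    def _population(self, rng, n=50):
        cfg = ScenarioConfig(scenario=2, cohort_size=n)
        pop = init_cohort(cfg, rng)
        for p in pop:
            p.age = 70
        return cfg, pop

    def test_removing_single_or_widow_triggers_no_cascade(self, rng):
        cfg, pop = self._population(rng)
        sched = MortalitySchedule(
            ages=np.arange(66, 93),
            removals=np.array([0] * 4 + [5] + [0] * 22),
            base=1000,
        )
        survivors, deaths = apply_mortality(pop, sched, cfg, rng)
        assert deaths == 5
        assert len(survivors) == len(pop) - 5
        assert not any(p.marital_status == "widow" for p in survivors)

    def test_married_death_widows_the_spouse(self, rng):
        cfg = ScenarioConfig(scenario=2)
        wife = Person(0, 78, "woman", 1, "married", AgePath(65.0))
        husband = Person(1, 79, "man", 0, "married", AgePath(64.0))
        wife.spouse, husband.spouse = husband, wife
        sched = MortalitySchedule(
            ages=np.arange(66, 93),
            removals=np.array([0] * 13 + [1] + [0] * 13),  # one death at 79
            base=1000,
        )
        survivors, deaths = apply_mortality([wife, husband], sched, cfg, rng)
        assert deaths == 1 and survivors == [wife]
        assert wife.marital_status == "widow"
        assert wife.ds == -1 and wife.historic == 1
        assert wife.spouse is None
        assert wife.age_path.spouse_death == 78
        # widowhood after 70 scatters remaining events at +5,+5,+2 lags
        assert wife.age_path.moving == 83
        assert wife.age_path.functional_decline == 88
        assert wife.age_path.institutionalization == 90

    def test_terminal_age_removes_everyone(self, rng):
        cfg, pop = self._population(rng)
        for p in pop:
            p.age = 93
        sched = MortalitySchedule(
            ages=np.arange(66, 93), removals=np.zeros(27, int), base=1000
        )
        survivors, deaths = apply_mortality(pop, sched, cfg, rng)
        assert survivors == [] and deaths == len(pop)


class TestTreatment:
    def test_noop_without_depressed_individuals(self, rng):
        cfg = ScenarioConfig(scenario=3, cohort_size=100)
        pop = [Person(i, 70, "man", 1, "single", AgePath(65.0)) for i in range(50)]
        _, sel, elig = apply_treatment(pop, cfg, rng)
        assert (sel, elig) == (0, 0)
        assert all(p.ds == 1 for p in pop)

    def test_selection_and_split_rates(self, rng):
        cfg = ScenarioConfig(scenario=3)
        pop = [Person(i, 70, "man", -1, "single", AgePath(65.0)) for i in range(100_000)]
        _, sel, elig = apply_treatment(pop, cfg, rng)
        assert elig == 100_000
        se = np.sqrt(0.169 * 0.831 / elig)
        assert abs(sel / elig - 0.169) < 3 * se
        recovered = [p.ds for p in pop if p.ds != -1]
        assert len(recovered) == sel
        frac_pos = np.mean([d == 1 for d in recovered])
        se = np.sqrt(0.25 / sel)
        assert abs(frac_pos - 0.5) < 3 * se


def small_schedule(fixture_spec, base):
    """Mortality schedule matched to a reduced cohort size."""
    from elderdep.fixtures import gen_mortality

    return compute_mortality_schedule(gen_mortality(fixture_spec), base=base)


class TestRunSimulation:
    def test_scenario1_all_neutral_impacts_keep_prevalence_zero(self, fixture_spec):
        cfg = ScenarioConfig(scenario=1, cohort_size=200, seed=0)
        res = run_simulation(cfg, degenerate_impact_set(1), small_schedule(fixture_spec, 200))
        np.testing.assert_array_equal(res.curve.prevalence, 0.0)

    def test_curve_covers_28_ages_within_unit_interval(self, table_set, fixture_spec):
        cfg = ScenarioConfig(scenario=2, cohort_size=300, seed=5)
        res = run_simulation(cfg, table_set, small_schedule(fixture_spec, 300))
        assert len(res.curve.ages) == 28
        assert res.curve.ages[0] == 65 and res.curve.ages[-1] == 92
        finite = res.curve.prevalence[np.isfinite(res.curve.prevalence)]
        assert np.all((finite >= 0) & (finite <= 1))

    def test_census_accounting_balances(self, table_set, schedule):
        cfg = ScenarioConfig(scenario=2, cohort_size=500, seed=2)
        res = run_simulation(cfg, table_set, schedule)
        assert res.injected - res.deaths == len(res.population)

    def test_spouse_links_stay_consistent_after_full_run(self, table_set, schedule):
        cfg = ScenarioConfig(scenario=2, cohort_size=500, seed=4)
        res = run_simulation(cfg, table_set, schedule)
        for p in res.population:
            if p.marital_status == "married":
                assert p.spouse is not None and p.spouse.alive and p.spouse.spouse is p
            else:
                assert p.spouse is None

    def test_fixed_seed_reproducibility(self, table_set, schedule):
        cfg = ScenarioConfig(scenario=2, cohort_size=300, seed=11)
        a = run_simulation(cfg, table_set, schedule)
        b = run_simulation(cfg, table_set, schedule)
        np.testing.assert_array_equal(a.curve.prevalence, b.curve.prevalence)

    def test_scenario2_all_neutral_impacts_accumulate_widowhood(self, schedule):
        # initial depressed stay depressed and each widow adds one more:
        # prevalence rises with age
        cfg = ScenarioConfig(scenario=2, cohort_size=1000, seed=8, n_replicates=5)
        summary = run_replicates(cfg, degenerate_impact_set(1), schedule)
        prev = summary.mean.prevalence
        assert np.mean(prev[-8:]) > np.mean(prev[:8])
        assert np.corrcoef(summary.mean.ages, prev)[0, 1] > 0.9


class TestReplicates:
    def test_single_replicate_mean_is_that_curve(self, table_set, schedule):
        cfg = ScenarioConfig(scenario=2, cohort_size=200, seed=6, n_replicates=1)
        summary = run_replicates(cfg, table_set, schedule)
        np.testing.assert_array_equal(summary.mean.prevalence, summary.curves[0].prevalence)

    def test_mean_equals_brute_force_average(self, table_set, schedule):
        cfg = ScenarioConfig(scenario=2, cohort_size=200, seed=6, n_replicates=4)
        summary = run_replicates(cfg, table_set, schedule)
        stacked = np.vstack([c.prevalence for c in summary.curves])
        manual = np.array(
            [np.nanmean(stacked[:, j]) for j in range(stacked.shape[1])]
        )
        np.testing.assert_allclose(summary.mean.prevalence, manual)


class TestPrevalenceCurve:
    def test_rejects_noncontiguous_ages(self):
        with pytest.raises(ValueError, match="contiguous"):
            PrevalenceCurve(ages=[65, 67, 68], prevalence=[0.1, 0.2, 0.3])

    def test_rejects_out_of_range_prevalence(self):
        with pytest.raises(ValueError, match="outside"):
            PrevalenceCurve(ages=[65, 66], prevalence=[0.1, 1.2])

    def test_csv_round_trip(self, tmp_path):
        curve = PrevalenceCurve(
            ages=np.arange(65, 70),
            prevalence=[0.1, 0.2, 0.15, 0.3, 0.25],
            ci_low=[0.05, 0.1, 0.1, 0.2, 0.2],
            ci_high=[0.15, 0.3, 0.2, 0.4, 0.3],
        )
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = PrevalenceCurve.from_csv(path, require_ci=True)
        np.testing.assert_array_equal(back.ages, curve.ages)
        np.testing.assert_allclose(back.prevalence, curve.prevalence)
        np.testing.assert_allclose(back.ci_high, curve.ci_high)
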