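"""Founder-based TMRCA estimators: hand values, identities, recovery."""

import numpy as np
import pytest
from scipy import stats

from ystrpop import (
    FounderAgeEstimator,
    FounderHaplotype,
    MutationRateTable,
    SimulationConfig,
    ValidationError,
    asd_quadratic_age,
    date_population,
    modal_founder,
    rho_statistic,
    simulate_star,
    to_years,
    weighted_rho,
)

from conftest import make_table


def root_for(table, repeats=None):
    if repeats is None:
        repeats = [20] * len(table.panel)
    return FounderHaplotype(
        repeats=tuple(repeats), panel=table.panel, selection_rule="user-supplied"
    )


def flat_rates(table, mu=0.002):
    return MutationRateTable(
        rates={l: mu for l in table.panel}, source_label="test"
    )


def expected_abs_displacement(lam):
    """Exact E|D| for a ±1 walk with Poisson(lam) steps: D ~ Skellam."""
    d = stats.skellam(lam / 2, lam / 2)
    ks = np.arange(-200, 201)
    return float(np.sum(np.abs(ks) * d.pmf(ks)))


class TestModalFounder:
    def test_identical_table_returns_that_haplotype(self):
        table = make_table({"DYS391": [12, 12, 12]}, "P")
        assert modal_founder(table).repeats[table.panel.index("DYS391")] == 12

    def test_majority_wins(self):
        table = make_table({"DYS391": [12, 12, 13]}, "P")
        assert modal_founder(table).repeats[table.panel.index("DYS391")] == 12

    def test_tie_broken_toward_smaller_repeat(self):
        table = make_table({"DYS391": [12, 12, 13, 13]}, "P")
        assert modal_founder(table).repeats[table.panel.index("DYS391")] == 12

    def test_empty_table_rejected(self):
        table = make_table({"DYS391": [12]}, "P")
        table.data = table.data.iloc[:0]
        with pytest.raises(ValidationError):
            modal_founder(table)


class TestRho:
    def test_zero_at_root(self):
        table = make_table({}, ["P"] * 5)
        rho, sd = rho_statistic(table, root_for(table))
        assert rho == 0.0 and sd == 0.0

    def test_half_step_mean(self):
        table = make_table({"DYS391": [20, 21]}, "P")
        rho, sd = rho_statistic(table, root_for(table))
        assert rho == pytest.approx(0.5)
        assert sd == pytest.approx(np.sqrt(0.5 / 2))

    def test_single_haplotype_warns(self):
        table = make_table({"DYS391": [21]}, "P")
        with pytest.warns(UserWarning, match="n = 1"):
            rho_statistic(table, root_for(table))

    def test_shift_invariance_including_root(self):
        table = make_table({"DYS391": [19, 21, 22]}, "P")
        shifted = make_table({"DYS391": [22, 24, 25]}, "P")
        r1, _ = rho_statistic(table, root_for(table))
        root2 = [20] * 15
        root2[table.panel.index("DYS391")] = 23
        r2, _ = rho_statistic(shifted, root_for(shifted, root2))
        assert r1 == pytest.approx(r2)


class TestWeightedRho:
    def test_equal_rates_reduce_to_rho(self):
        table = make_table({"DYS391": [20, 22, 21], "DYS458": [19, 20, 20]}, "P")
        root = root_for(table)
        rho, _ = rho_statistic(table, root)
        res = weighted_rho(table, root, flat_rates(table, 0.002))
        assert res["rho_w"] == pytest.approx(rho, abs=1e-12)
        assert res["age_generations"] == pytest.approx(rho / (15 * 0.002), abs=1e-9)

    def test_slow_locus_mutations_age_older_than_mean_rate_dating(self):
        # two-locus toy: all divergence at the slow locus
        from ystrpop import HaplotypeTable

        table = HaplotypeTable.from_arrays(
            np.array([[20, 20], [22, 20]]),
            panel=("SLOW", "FAST"),
            populations="P",
        )
        root = FounderHaplotype(repeats=(20, 20), panel=("SLOW", "FAST"),
                                selection_rule="user-supplied")
        rates = MutationRateTable(rates={"SLOW": 0.001, "FAST": 0.004})
        res = weighted_rho(table, root, rates)
        rho, _ = rho_statistic(table, root)
        mean_rate_age = rho / (2 * 0.0025)
        assert res["age_generations"] > mean_rate_age
        # d_bar = 1 at SLOW only: T = (1/2)(1/0.001) = 500
        assert res["age_generations"] == pytest.approx(500.0)

    def test_zero_distance_zero_age(self):
        table = make_table({}, ["P"] * 3)
        res = weighted_rho(table, root_for(table), flat_rates(table))
        assert res["age_generations"] == 0.0

    def test_missing_rate_is_lookup_error(self):
        table = make_table({"DYS391": [20, 21]}, "P")
        partial = MutationRateTable(rates={"DYS391": 0.002})
        with pytest.raises(LookupError):
            weighted_rho(table, root_for(table), partial)


class TestAsdDating:
    def test_zero_at_root(self):
        table = make_table({}, ["P"] * 3)
        res = asd_quadratic_age(table, root_for(table), flat_rates(table))
        assert res["age_generations"] == 0.0

    def test_plus_minus_one_pair(self):
        from ystrpop import HaplotypeTable

        table = HaplotypeTable.from_arrays(
            np.array([[21], [19]]), panel=("L",), populations="P"
        )
        root = FounderHaplotype(repeats=(20,), panel=("L",),
                                selection_rule="user-supplied")
        rates = MutationRateTable(rates={"L": 0.002})
        res = asd_quadratic_age(table, root, rates)
        assert res["asd"] == pytest.approx(1.0)
        assert res["age_generations"] == pytest.approx(1 / 0.002)

    def test_star_simulation_recovery(self):
        """Second-moment dating is unbiased on star genealogies: the
        mean estimate over replicates lands within 3 SE of the truth."""
        loci = {f"L{i}": 0.002 for i in range(15)}
        T = 300.0
        ages = []
        for rep in range(200):
            table = simulate_star(
                SimulationConfig(n=100, loci=dict(loci), tmrca=T, seed=900 + rep)
            )
            root = FounderHaplotype(repeats=tuple([20] * 15),
                                    panel=table.panel,
                                    selection_rule="user-supplied")
            rates = MutationRateTable(rates=dict(loci))
            ages.append(asd_quadratic_age(table, root, rates)["age_generations"])
        ages = np.array(ages)
        sem = ages.std(ddof=1) / np.sqrt(len(ages))
        assert abs(ages.mean() - T) < 3 * sem


def test_rho_matches_exact_smm_expectation():
    """mean rho over replicates equals the closed-form SMM expectation
    L * E|Skellam| — the statistic under-counts T*Sum(mu) by exactly the
    multi-hit fraction, and the implementation reproduces the theory."""
    mu, T, L = 0.002, 200.0, 15
    loci = {f"L{i}": mu for i in range(L)}
    rhos = []
    for rep in range(200):
        table = simulate_star(
            SimulationConfig(n=50, loci=dict(loci), tmrca=T, seed=4000 + rep)
        )
        root = FounderHaplotype(repeats=tuple([20] * L), panel=table.panel,
                                selection_rule="user-supplied")
        rhos.append(rho_statistic(table, root)[0])
    rhos = np.array(rhos)
    expect = L * expected_abs_displacement(mu * T)
    sem = rhos.std(ddof=1) / np.sqrt(len(rhos))
    assert abs(rhos.mean() - expect) < 3 * sem
    # and the naive target T*Sum(mu) overstates it (back-mutation bias)
    assert expect < T * mu * L


def test_rho_sd_formula_tracks_empirical_sd():
    """sqrt(rho/n) approximates the replicate-to-replicate SD of rho
    within a factor of 1.5 on star genealogies."""
    loci = {f"L{i}": 0.002 for i in range(15)}
    rhos, sds = [], []
    for rep in range(200):
        table = simulate_star(
            SimulationConfig(n=50, loci=dict(loci), tmrca=100, seed=7000 + rep)
        )
        root = FounderHaplotype(repeats=tuple([20] * 15), panel=table.panel,
                                selection_rule="user-supplied")
        rho, sd = rho_statistic(table, root)
        rhos.append(rho)
        sds.append(sd)
    empirical = np.std(rhos, ddof=1)
    formula = np.mean(sds)
    assert formula / 1.5 < empirical < formula * 1.5


class TestToYears:
    @pytest.mark.parametrize("gen,gt,years", [(100, 30, 3000), (0, 25, 0)])
    def test_products(self, gen, gt, years):
        exact, display = to_years(gen, gt)
        assert exact == pytest.approx(years) and display == years

    def test_30_over_25_ratio_exact(self):
        t = 77.7
        assert to_years(t, 30)[0] / to_years(t, 25)[0] == pytest.approx(1.2)

    def test_invalid_generation_time(self):
        with pytest.raises(ValidationError):
            to_years(10, 0)


class TestFounderAgeEstimator:
    def test_monomorphic_population_all_ages_zero(self):
        table = make_table({}, ["P"] * 5)
        est = FounderAgeEstimator(
            rates={l: 0.002 for l in table.panel}, random_state=0
        ).fit(table)
        assert (est.report_["generations"] == 0).all()
        assert (est.report_["years"] == 0).all()

    def test_star_truth_within_three_estimator_sd(self):
        loci = {f"L{i}": 0.002 for i in range(15)}
        T = 100.0
        table = simulate_star(
            SimulationConfig(n=50, loci=dict(loci), tmrca=T, seed=11)
        )
        est = FounderAgeEstimator(
            rates=dict(loci), founder=[20] * 15, random_state=0
        ).fit(table)
        for _, row in est.report_.iterrows():
            assert abs(row["generations"] - T) < 3 * max(row["sd_generations"], 5)

    def test_report_has_both_generation_times(self, two_pop_table):
        est = FounderAgeEstimator(
            rates={l: 0.002 for l in two_pop_table.panel},
            n_bootstrap=100,
            random_state=0,
        ).fit(two_pop_table.for_population("A"))
        assert sorted(est.report_["generation_time"].unique()) == [25.0, 30.0]
        assert set(est.report_["method"]) == {"rho", "weighted_rho", "asd_quadratic"}
        # years = generations x generation time, row by row
        assert np.allclose(
            est.report_["years"],
            est.report_["generations"] * est.report_["generation_time"],
        )


def test_date_population_per_population_rows(two_pop_table):
    report = date_population(
        two_pop_table,
        {l: 0.002 for l in two_pop_table.panel},
        n_bootstrap=50,
        random_state=1,
    )
    assert set(report["population"]) == {"A", "B"}
    assert (report["generations"] >= 0).all()
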