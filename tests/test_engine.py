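"""Population-level engine behavior: Wright-Fisher reduction, bookkeeping
invariants, phase logic and demography."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from polyadapt.sim_engine import (DemographyModel, Population, QTLLayout,
                                  TraitParams, advance_generation,
                                  demography_grid, run_adaptation, run_burn_in)

PARAMS = TraitParams(sigma_m=0.05, v_s=1.0)


def single_site_population(n, count, effect=0.0, neutral=True):
    """Population with one segregating mutation at a given allele count and
    no further mutational input."""
    quiet = dataclasses.replace(QTLLayout(), u_gamete=0.0)
    pop = Population.founder(n, PARAMS, quiet, generation=0, neutral=neutral)
    geno = np.zeros((2 * n, 1), dtype=bool)
    geno[:count, 0] = True
    pop.geno = geno
    pop.mut_id = np.array([0], dtype=np.int64)
    pop.mut_locus = np.array([5], dtype=np.int64)
    pop.mut_position = np.array([12_000.0])
    pop.mut_effect = np.array([effect])
    pop.mut_origin = np.array([0], dtype=np.int64)
    pop.next_id = 1
    gv = 0.5 * (pop.geno @ pop.mut_effect)
    pop.G = gv[0::2] + gv[1::2]
    pop.P = pop.G.copy()
    return pop


class TestWrightFisherReduction:
    def test_neutral_allele_frequency_increments(self, rng):
        # with all effects zero, one generation of reproduction is binomial
        # sampling: E[dp] = 0, Var[dp] = p(1-p)/2N
        n, p0 = 200, 0.3
        base = single_site_population(n, count=int(p0 * 2 * n))
        deltas = []
        for _ in range(3000):
            pop = base.copy()
            advance_generation(pop, rng)
            deltas.append(pop.geno.sum() / (2 * n) - p0)
        deltas = np.asarray(deltas)
        expected_var = p0 * (1 - p0) / (2 * n)
        assert abs(deltas.mean()) < 4 * np.sqrt(expected_var / len(deltas))
        assert np.var(deltas) == pytest.approx(expected_var, rel=0.12)

    def test_constant_schedule_keeps_size(self, rng):
        pop = Population.founder(50, PARAMS, QTLLayout(), generation=0)
        advance_generation(pop, rng)
        assert pop.n_individuals == 50
        advance_generation(pop, rng, n_next=80)
        assert pop.n_individuals == 80


class TestBookkeeping:
    def test_genetic_values_recomputable_from_gametes(self, rng):
        pop, _ = run_burn_in(PARAMS, QTLLayout(), 100, rng, generations=400)
        assert np.allclose(pop.recompute_G(), pop.G, atol=1e-10)

    def test_allele_counts_match_gamete_tally(self, rng):
        pop, _ = run_burn_in(PARAMS, QTLLayout(), 100, rng, generations=300)
        table = pop.segregating_table()
        assert np.array_equal(table["count"].to_numpy(), pop.geno.sum(axis=0))
        assert np.all((table["count"] > 0) & (table["count"] < pop.n_gametes))

    def test_fixed_effects_persist_in_baseline(self, rng):
        pop, _ = run_burn_in(PARAMS, QTLLayout(), 60, rng, generations=1200)
        fixed = pop.fixation_table()
        assert pop.baseline == pytest.approx(fixed["effect"].sum())
        # baseline is part of every genetic value
        assert np.allclose(pop.recompute_G(), pop.G, atol=1e-10)

    def test_no_mutation_means_no_variance(self, rng):
        quiet = dataclasses.replace(QTLLayout(), u_gamete=0.0)
        pop, traj = run_burn_in(PARAMS, quiet, 50, rng, generations=200)
        assert np.all(traj["var_g"] == 0.0)
        assert pop.n_segregating == 0

    def test_all_zero_fitness_rejected(self, rng):
        pop = Population.founder(10, TraitParams(sigma_m=0.05, v_s=1e-4), QTLLayout())
        pop.P = np.full(10, 1e6)  # absurd trait values underflow w to 0
        with pytest.raises(RuntimeError):
            advance_generation(pop, rng)


class TestDemographyModel:
    def test_schedule_endpoints_and_growth(self):
        dem = DemographyModel(n_anc=1000, bottleneck_fraction=0.05, final_multiple=10)
        assert dem.size(0) == dem.n_bottleneck == 50
        assert dem.size(dem.n_generations) == dem.n_final == 10_000
        sizes = dem.sizes()
        assert np.all(np.diff(sizes) >= 0)
        # exponential interpolation: log sizes roughly linear
        logs = np.log(sizes.astype(float))
        assert np.allclose(np.diff(logs), logs[-1] / dem.n_generations - logs[0] / dem.n_generations,
                           atol=0.05)

    def test_grid_has_twelve_scenarios(self):
        grid = demography_grid(500)
        assert len(grid) == 12
        assert len({d.scenario_id for d in grid}) == 12

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            DemographyModel(n_anc=1)
        with pytest.raises(ValueError):
            DemographyModel(n_anc=100, bottleneck_fraction=0.0)


class TestAdaptationPhase:
    def test_null_shift_never_triggers_truncation(self, rng):
        params = TraitParams(sigma_m=0.05, v_s=1.0, z_opt_new=0.0)
        pop, _ = run_burn_in(params, QTLLayout(), 80, rng, generations=400)
        res = run_adaptation(pop, DemographyModel.constant(80), rng)
        assert (res.trajectory["phase"] == "stabilizing").all()
        assert res.trajectory["mean_trait"].abs().max() < 1.0

    def test_truncation_until_mean_reaches_optimum(self, rng):
        params = TraitParams(sigma_m=0.3, v_s=5.0)
        pop, _ = run_burn_in(params, QTLLayout(), 300, rng)
        dem = DemographyModel(n_anc=300, n_generations=150)
        res = run_adaptation(pop, dem, rng)
        traj = res.trajectory
        assert res.reached_optimum
        # truncation phase is a prefix of the run, stabilizing afterwards
        phases = traj["phase"].to_numpy()
        switch = np.nonzero(phases == "stabilizing")[0]
        assert switch.size > 0
        first = switch[0]
        assert (phases[:first] == "truncation").all()
        assert (phases[first:] == "stabilizing").all()
        # mean at the switch generation had reached the optimum
        assert traj["mean_trait"].iloc[first - 1] >= params.z_opt_new

    def test_positive_alleles_rise_negative_fall_under_truncation(self, rng):
        params = TraitParams(sigma_m=0.1, v_s=1.0)
        pop, _ = run_burn_in(params, QTLLayout(), 300, rng, generations=3000)
        start = pop.segregating_table().set_index("mutation_id")
        for _ in range(15):
            advance_generation(pop, rng, z_opt=params.z_opt_new, phase="truncation")
        end = pop.segregating_table().set_index("mutation_id")
        joined = start.join(end["frequency"], rsuffix="_after")
        # fixed alleles rose to 1, lost fell to 0
        fixed_ids = {f[0] for f in pop.fixations}
        joined["frequency_after"] = joined["frequency_after"].fillna(
            joined.index.to_series().isin(fixed_ids).astype(float))
        delta = joined["frequency_after"] - joined["frequency"]
        pos = joined["effect"] > 0
        assert delta[pos].mean() > 0
        assert delta[~pos].mean() < 0

    def test_bottleneck_and_snapshot_cadence(self, rng):
        params = TraitParams(sigma_m=0.1, v_s=1.0)
        pop, _ = run_burn_in(params, QTLLayout(), 200, rng, generations=1000)
        dem = DemographyModel(n_anc=200, bottleneck_fraction=0.1,
                              final_multiple=1.0, n_generations=150)
        res = run_adaptation(pop, dem, rng)
        gens = [s.generation for s in res.snapshots]
        assert gens == [0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 150]
        assert len(res.snapshots[0].g_values) == dem.n_bottleneck
        # stored snapshot G values recompute from the mutation table exactly
        snap = res.snapshots[-1]
        assert len(snap.g_values) == dem.size(150)

    def test_fixation_records_have_positive_sojourn_and_init_freq(self, rng):
        params = TraitParams(sigma_m=0.3, v_s=5.0)
        pop, _ = run_burn_in(params, QTLLayout(), 200, rng)
        res = run_adaptation(pop, DemographyModel.constant(200), rng)
        fix = res.fixations
        if len(fix):
            assert (fix["sojourn"] >= 1).all()
            standing = fix["origin_generation"] <= 0
            assert (fix.loc[standing, "initial_frequency"] > 0).all()
            assert (fix.loc[~standing, "initial_frequency"] == 0).all()
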