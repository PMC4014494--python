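"""Unit tests for the individual-based population simulator."""
import numpy as np
import pytest
from dataclasses import replace

from popchaos import (DoseResponse, LifeHistoryParams, PopulationState,
                      TreatmentConfig, classify_by_length, initial_state,
                      reproduction_inhibition, run_ensemble, run_simulation,
                      step_day)


class TestReproductionInhibition:
    def test_zero_dose_is_zero(self):
        assert reproduction_inhibition(0.0, DoseResponse()) == 0.0

    def test_half_effect_at_ec50(self):
        dr = DoseResponse(ec50_repro=7.3, hill_slope=1.9)
        assert reproduction_inhibition(7.3, dr) == pytest.approx(0.5)

    def test_hand_computed_value(self):
        # 20²/(20²+10²) = 400/500
        dr = DoseResponse(ec50_repro=10.0, hill_slope=2.0)
        assert reproduction_inhibition(20.0, dr) == pytest.approx(0.8)

    def test_strictly_increasing_and_bounded(self):
        dr = DoseResponse()
        vals = [reproduction_inhibition(c, dr) for c in (0, 1, 5, 20, 100, 1e6)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            reproduction_inhibition(-1.0, DoseResponse())


class TestClassifyByLength:
    @pytest.mark.parametrize("lengths, expected", [
        ([1.0, 1.4, 2.6], (1, 1, 1)),
        ([], (0, 0, 0)),
        ([1.39, 1.40, 2.59, 2.60], (1, 2, 1)),
        ([0.8] * 5 + [3.0] * 3, (5, 0, 3)),
    ])
    def test_boundaries(self, lengths, expected):
        assert classify_by_length(lengths) == expected

    def test_counts_partition_input(self, rng):
        lengths = rng.uniform(0.5, 4.0, size=200)
        assert sum(classify_by_length(lengths)) == 200

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            classify_by_length([1.0, 0.0])


def _state_with(lengths, ages=None, lifetimes=None, brood=None, food=1e6):
    n = len(lengths)
    return PopulationState(
        day=0,
        age=np.array(ages if ages is not None else [1] * n),
        length=np.array(lengths, dtype=float),
        max_lifetime=np.array(lifetimes if lifetimes is not None else [999] * n),
        days_since_brood=np.array(brood if brood is not None else [0] * n),
        days_starved=np.zeros(n, dtype=int),
        food=food,
    )


class TestStepDay:
    def test_extinction_is_absorbing_and_food_accumulates(self):
        cfg = TreatmentConfig(life_history=LifeHistoryParams(food_cap=None))
        state = PopulationState.empty(day=3, food=5.0)
        nxt = step_day(state, cfg, np.random.default_rng(0))
        assert nxt.size == 0
        assert nxt.day == 4
        assert nxt.food == 5.0 + cfg.life_history.food_input

    def test_ripe_adult_releases_full_brood_without_toxicant(self):
        lh = LifeHistoryParams(food_cap=None)  # superabundant food
        cfg = TreatmentConfig(concentration=0.0, life_history=lh)
        state = _state_with([3.0], brood=[lh.brood_interval], food=1e6)
        nxt = step_day(state, cfg, np.random.default_rng(1))
        neo = int(np.sum(nxt.length == lh.length_at_birth))
        # ration ≈ 1 under superabundant food → brood of max size
        assert neo == lh.max_brood_size
        assert nxt.size == 1 + lh.max_brood_size

    def test_inhibition_shrinks_brood(self):
        lh = LifeHistoryParams(food_cap=None)
        dr = DoseResponse(ec50_repro=10.0, hill_slope=1.0)
        cfg = TreatmentConfig(concentration=10.0, life_history=lh,
                              dose_response=dr)
        state = _state_with([3.0], brood=[lh.brood_interval], food=1e6)
        nxt = step_day(state, cfg, np.random.default_rng(1))
        neo = int(np.sum(nxt.length == lh.length_at_birth))
        assert neo == round(lh.max_brood_size * 0.5)

    def test_lifetime_rule_removes_individual(self):
        cfg = TreatmentConfig()
        state = _state_with([3.0, 2.0], ages=[40, 5], lifetimes=[40, 50])
        nxt = step_day(state, cfg, np.random.default_rng(2))
        assert nxt.size == 1
        assert nxt.age[0] == 6

    def test_growth_is_monotone_and_bounded(self):
        lh = LifeHistoryParams()
        cfg = TreatmentConfig(life_history=lh)
        state = _state_with([0.8, 2.0, 3.9], food=1e6)
        nxt = step_day(state, cfg, np.random.default_rng(3))
        grown = nxt.length[nxt.age > 0]
        assert np.all(grown >= np.array([0.8, 2.0, 3.9]))
        assert np.all(grown <= lh.asymptotic_length)

    def test_constant_population_without_birth_and_death(self):
        lh = LifeHistoryParams(max_brood_size=0, lifetime_range=(10**6, 10**6),
                               starvation_ration=0.0)
        cfg = TreatmentConfig(n_days=80, life_history=lh)
        s = run_simulation(cfg, seed=5)
        assert np.all(s.total == 8)


class TestRunSimulation:
    def test_day_zero_census(self):
        s = run_simulation(TreatmentConfig(n_days=1), seed=0)
        assert (s.neonates[0], s.juveniles[0], s.adults[0]) == (5, 0, 3)

    def test_series_length_and_conservation(self, small_treatment):
        s = run_simulation(small_treatment, seed=1)
        assert len(s) == small_treatment.n_days + 1
        assert np.array_equal(s.total, s.neonates + s.juveniles + s.adults)
        assert np.all(s.total >= 0)

    def test_zero_food_drives_extinction(self):
        lh = LifeHistoryParams(food_input=0.0, initial_food=0.0)
        s = run_simulation(TreatmentConfig(n_days=365, life_history=lh), seed=2)
        assert s.total[-1] == 0

    def test_same_seed_bit_identical(self, small_treatment):
        a = run_simulation(small_treatment, seed=9)
        b = run_simulation(small_treatment, seed=9)
        for field in ("neonates", "juveniles", "adults"):
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_control_is_bounded_nonextinct_nonconstant(self):
        cfg = TreatmentConfig(n_days=365)
        s = run_simulation(cfg, seed=3)
        post = s.total[50:]
        assert s.total[-1] > 0
        assert post.max() < cfg.life_history.carrying_ceiling
        assert post.std() > 0


class TestRunEnsemble:
    def test_runs_diverge(self, small_treatment):
        """Distinct lifetime draws push trajectories apart once the first
        founders reach their maximum lifetimes."""
        ens = run_ensemble(small_treatment)
        trajectories = {tuple(s.total) for s in ens}
        assert len(trajectories) == len(ens)

    def test_seed_pairing_across_concentrations(self, small_treatment):
        c40 = replace(small_treatment, concentration=40.0)
        a = run_ensemble(small_treatment)
        b = run_ensemble(c40)
        assert [s.seed for s in a] == [s.seed for s in b]
        # identical founding lifetime draws at every paired seed
        for s in a:
            ia = initial_state(small_treatment, np.random.default_rng(s.seed))
            ib = initial_state(c40, np.random.default_rng(s.seed))
            assert np.array_equal(ia.max_lifetime, ib.max_lifetime)

    def test_single_run_rejected(self, small_treatment):
        with pytest.raises(ValueError):
            run_ensemble(replace(small_treatment, n_runs=1))

    def test_monotone_stress_on_late_abundance(self):
        """Mean late-window abundance does not increase with concentration."""
        means = []
        for c in (0.0, 10.0, 40.0):
            cfg = TreatmentConfig(concentration=c, n_days=365, n_runs=20)
            ens = run_ensemble(cfg)
            means.append(np.mean([s.total[200:].mean() for s in ens]))
        assert means[0] >= means[1] >= means[2]
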