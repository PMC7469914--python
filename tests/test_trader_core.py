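import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from drugtrader.interaction_store import Candidate, CandidateDataset, EffectLabel, HTTargetSet
from drugtrader.trader_core import (
    INFEASIBLE,
    CandidateSolution,
    InvalidSelectionError,
    Scorer,
    TraderConfig,
    distributing,
    importing_exporting,
    init_population,
    largest_remainder_allocation,
    retailing,
    run_trader,
    score,
    update_group_sizes,
)
from drugtrader.synthetic_data import GeneratorSpec, generate


def _cfg(**kw):
    defaults = dict(population_size=8, trader_count=2, max_evaluations=500, seed=0)
    defaults.update(kw)
    return TraderConfig(**defaults)


def _single_candidate_dataset():
    return CandidateDataset(
        "g",
        HTTargetSet([("T1", EffectLabel.INH)]),
        [Candidate("d1", frozenset({"T1"}), 0)],
    )


class TestScore:
    def test_singleton_full_coverage_no_side_effects(self, small_dataset):
        cs = CandidateSolution.from_variables([1, 0, 0])
        assert score(cs, small_dataset) == pytest.approx(1.0)

    def test_two_drug_hand_arithmetic(self, small_dataset):
        # coverage {T1} u {T2} = 2 targets, side effects 0 + 4 over 2 drugs
        cs = CandidateSolution.from_variables([1, 0, 1])
        assert score(cs, small_dataset) == pytest.approx(2 - 4 / 2)

    def test_adverse_pair_is_infeasible_under_hard_mode(self, small_dataset):
        # one violating pair: sentinel region, graded by violation count so
        # the search can rank infeasible selections
        cs = CandidateSolution.from_variables([0, 1, 1])
        assert score(cs, small_dataset) == INFEASIBLE - 1
        assert score(cs, small_dataset) <= INFEASIBLE

    def test_adverse_pair_penalized_under_soft_mode(self, small_dataset):
        cfg = _cfg(ddar_mode="penalty", penalty=10.0)
        cs = CandidateSolution.from_variables([0, 1, 1])
        base = 1 - (2 + 4) / 2  # one covered target, mean side effects 3
        assert score(cs, small_dataset, cfg) == pytest.approx(base - 10.0)

    def test_all_zero_selection_rejected(self, small_dataset):
        with pytest.raises(InvalidSelectionError):
            score(CandidateSolution.from_variables([0, 0, 0]), small_dataset)

    def test_scorer_counts_evaluations(self, small_dataset):
        scorer = Scorer(small_dataset)
        for _ in range(7):
            scorer.score_mask(0b001)
        assert scorer.calls == 7


class TestInitPopulation:
    def test_round_robin_equal_groups(self, small_dataset):
        state = init_population(3, _cfg(), small_dataset)
        assert [len(g) for g in state.groups] == [4, 4]
        assert state.evaluations_used == 8

    def test_length_one_forces_repair_to_one(self):
        ds = _single_candidate_dataset()
        state = init_population(1, _cfg(), ds)
        assert all(sol.variables == [1] for sol in state.population)

    def test_fixed_seed_reproducible(self, small_dataset):
        a = init_population(3, _cfg(seed=42), small_dataset)
        b = init_population(3, _cfg(seed=42), small_dataset)
        assert [s.mask for s in a.population] == [s.mask for s in b.population]
        assert [s.score for s in a.population] == [s.score for s in b.population]

    def test_budget_below_population_is_config_error(self):
        with pytest.raises(ValueError):
            _cfg(max_evaluations=4)


class TestGroupSizes:
    def test_largest_remainder_frozen_example(self):
        # pool C - M*T = 32 distributed over shifted properties 10:20:30:40;
        # frozen from direct evaluation of the proportional shares
        shares = largest_remainder_allocation([10, 20, 30, 40], 32)
        assert shares == [3, 6, 10, 13]
        assert [2 + s for s in shares] == [5, 8, 12, 15]

    def test_allocation_always_sums_to_pool(self):
        rng = random.Random(0)
        for _ in range(50):
            n = rng.randint(2, 8)
            weights = [rng.random() + 1e-9 for _ in range(n)]
            pool = rng.randint(0, 60)
            shares = largest_remainder_allocation(weights, pool)
            assert sum(shares) == pool
            assert all(s >= 0 for s in shares)

    def test_equal_properties_equal_sizes(self, small_dataset):
        state = init_population(3, _cfg(), small_dataset)
        for sol in state.population:
            sol.score = 1.0
        targets = update_group_sizes(state, state.cfg)
        assert targets == [4, 4]
        assert [len(g) for g in state.groups] == [4, 4]

    def test_floor_only_population_ignores_properties(self, small_dataset):
        cfg = _cfg(population_size=4, trader_count=2)
        state = init_population(3, cfg, small_dataset)
        state.population[0].score = 100.0
        assert update_group_sizes(state, cfg) == [2, 2]

    def test_masters_never_migrate_and_sizes_sum(self, small_dataset):
        cfg = _cfg(population_size=10, trader_count=3, max_evaluations=1000, seed=3)
        state = init_population(3, cfg, small_dataset)
        masters_before = set(state.masters())
        # skew properties hard toward group 0
        for i in state.groups[0]:
            state.population[i].score = 50.0
        update_group_sizes(state, cfg)
        assert sum(len(g) for g in state.groups) == cfg.population_size
        assert all(len(g) >= cfg.min_members for g in state.groups)
        for gi, g in enumerate(state.groups):
            for master in masters_before & set(g):
                assert state.population[master].group == gi
        # every master still lives in a group
        assert masters_before <= set().union(*map(set, state.groups))


class TestOperators:
    @pytest.fixture
    def state(self, small_dataset):
        return init_population(3, _cfg(seed=7), small_dataset)

    def test_retailing_flip_count_bound(self, state):
        # m = 3 -> R = ceil(3/10) = 1: a rejected trial leaves the slave
        # untouched; an accepted one differs by the single flip (two bits
        # only when flipping the last set bit triggered the zero repair)
        slave = state.population[0]
        for _ in range(20):
            before = slave.mask
            changed = retailing(slave, state)
            dist = (before ^ slave.mask).bit_count()
            if not changed:
                assert dist == 0
            else:
                assert dist in (1, 2)
                assert dist == 1 or before.bit_count() == 1

    def test_retailing_improvement_only(self, state):
        slave = state.population[0]
        for _ in range(30):
            before_score = slave.score
            retailing(slave, state)
            assert slave.score >= before_score

    def test_retailing_accepted_flip_strictly_improves(self, state):
        slave = state.population[0]
        improved = [slave.score]
        for _ in range(30):
            if retailing(slave, state):
                assert slave.score > improved[-1]
                improved.append(slave.score)

    def test_distributing_full_copy_and_identical_noop(self):
        # strictly unimodal instance: 0b001 is the unique optimum, so the
        # slave converges to an exact clone of the master
        ds = CandidateDataset(
            "g",
            HTTargetSet([("T1", EffectLabel.INH)]),
            [
                Candidate("e1", frozenset({"T1"}), 0),
                Candidate("e2", frozenset({"T1"}), 3),
                Candidate("e3", frozenset({"T1"}), 5),
            ],
        )
        state = init_population(3, _cfg(seed=1), ds)
        master, slave = state.population[0], state.population[1]
        master.group = slave.group = 0
        scorer = Scorer(ds)
        master.mask, master.score = 0b001, scorer.score_mask(0b001)
        slave.mask, slave.score = 0b110, scorer.score_mask(0b110)
        rng = random.Random(0)
        for _ in range(500):
            if slave.mask == master.mask:
                break
            distributing(master, slave, state, rng)
        assert slave.mask == master.mask
        assert slave.score == master.score
        # identical master and slave: no trial can improve
        assert not distributing(master, slave, state, rng)
        assert slave.mask == master.mask

    def test_distributing_requires_shared_group(self, state):
        a, b = state.population[0], state.population[1]
        a.group, b.group = 0, 1
        with pytest.raises(ValueError):
            distributing(a, b, state)

    def test_importing_exporting_distinct_groups_required(self, state):
        a, b = state.population[0], state.population[1]
        a.group = b.group = 0
        with pytest.raises(ValueError):
            importing_exporting(a, b, state)

    def test_importing_exporting_copies_and_reverts(self, small_dataset):
        state = init_population(3, _cfg(seed=5), small_dataset)
        imp, exp = state.population[0], state.population[1]
        imp.group, exp.group = 0, 1
        exp.mask, exp.score = 0b001, Scorer(small_dataset).score_mask(0b001)
        imp.mask, imp.score = 0b001, exp.score  # importer already optimal
        rng = random.Random(2)
        for _ in range(10):
            assert not importing_exporting(imp, exp, state, rng)
            assert imp.mask == 0b001  # reverted every time

    def test_variables_remain_binary_under_all_operators(self, state):
        rng = random.Random(9)
        for _ in range(50):
            slave = state.population[rng.randrange(len(state.population))]
            retailing(slave, state, rng)
            assert set(slave.variables) <= {0, 1}
            assert len(slave.variables) == 3


class TestRunTrader:
    def test_unique_optimum_single_candidate(self):
        ds = _single_candidate_dataset()
        res = run_trader(ds, _cfg(max_evaluations=20))
        assert res.objective == pytest.approx(-1.0)
        assert res.selected == ["d1"]
        assert res.feasible

    def test_same_seed_identical_trace(self, small_dataset):
        cfg = _cfg(max_evaluations=400, seed=11)
        a = run_trader(small_dataset, cfg)
        b = run_trader(small_dataset, cfg)
        assert a.trace == b.trace
        assert a.variables == b.variables
        assert a.evaluations_used == b.evaluations_used

    def test_best_objective_monotone_along_trace(self):
        ds = generate(GeneratorSpec(n_candidates=12, n_main_targets=3, seed=5))
        res = run_trader(ds, TraderConfig(max_evaluations=3000, seed=4))
        assert all(b <= a + 1e-12 for a, b in zip(res.trace, res.trace[1:]))

    def test_evaluation_budget_respected(self):
        ds = generate(GeneratorSpec(n_candidates=15, n_main_targets=4, seed=6))
        cfg = TraderConfig(max_evaluations=777, seed=0)
        res = run_trader(ds, cfg)
        assert res.evaluations_used <= cfg.max_evaluations
        assert res.evaluations_used >= cfg.max_evaluations - cfg.population_size

    def test_reported_solution_feasible_under_hard_mode(self):
        ds = generate(
            GeneratorSpec(n_candidates=12, n_main_targets=3, ddar_density=0.3, seed=8)
        )
        res = run_trader(ds, TraderConfig(max_evaluations=2000, seed=1))
        scorer = Scorer(ds)
        mask = sum(v << i for i, v in enumerate(res.variables))
        assert scorer.feasible(mask)
        assert res.feasible

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(seed=st.integers(0, 10_000))
    def test_group_invariants_hold_throughout(self, seed):
        ds = generate(GeneratorSpec(n_candidates=6, n_main_targets=2, seed=99))
        cfg = _cfg(max_evaluations=200, seed=seed)
        state = init_population(6, cfg, ds)
        rng = random.Random(seed)
        for _ in range(5):
            for gi, g in enumerate(state.groups):
                master = state.population[state.masters()[gi]]
                for i in list(g):
                    sol = state.population[i]
                    if sol is master:
                        continue
                    distributing(master, sol, state, rng)
                    retailing(sol, state, rng)
            update_group_sizes(state, cfg)
            assert sum(len(g) for g in state.groups) == cfg.population_size
            assert all(len(g) >= cfg.min_members for g in state.groups)
            assert sorted(i for g in state.groups for i in g) == list(
                range(cfg.population_size)
            )
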