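"""The Trader discrete optimizer for drug-combination selection.

A candidate solution is a binary vector over the candidate drugs (1 = the
drug is part of the proposed combination).  Its score, maximized internally,
is

    score = AT - (sum of SE_i over selected drugs) / (number selected)

where AT is the number of distinct main targets jointly covered by the
selection and SE_i is drug i's side-effect count.  A good combination covers
many of the substituted drug's disease targets while keeping the *average*
side-effect load low.  All reports negate the score so that printed
objectives follow the lower-is-better convention (a perfect single-target
zero-side-effect substitute reports -1.0).

The population of solutions is organized into trader groups.  Each group has
a master (its best solution) and slaves; a trader's property is the sum of
its members' scores.  Three operators evolve the population, all under
improvement-only acceptance (a change is kept only if the re-scored solution
is strictly better, otherwise the previous variables are restored):

* retailing    -- a slave flips a small random set of bits (at most one
                  tenth of the vector length, minimum one);
* distributing -- a slave copies a random set of positions from its group's
                  master;
* importing-exporting -- a master copies a random set of positions from
                  another group's master.

After the operators run, group sizes are reallocated proportionally to the
traders' properties: every group keeps a floor of M = 2 members (no trader
is ever eliminated) and the remaining C - M*T slots are shared in proportion
to positive-shifted properties, with largest-remainder rounding so the
counts sum exactly to the population size.  Members migrate worst-first from
shrinking to growing groups; masters never migrate.

Termination is budget-based: the algorithm stops once the configured number
of score-function evaluations has been spent, which makes comparisons with
other optimizers fair ("same number of score functions").

Drug-drug adverse reactions constrain the search: under the default hard
mode any selection containing an adverse pair is infeasible (it receives a
sentinel score and can never become the incumbent); a soft mode instead
subtracts a penalty per violating pair.

Selections are stored as integer bitmasks: scoring is the inner loop and
bit operations keep it cheap even over millions of evaluations.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

from .interaction_store import CandidateDataset

__all__ = [
    "INFEASIBLE",
    "InvalidSelectionError",
    "CandidateSolution",
    "TraderConfig",
    "TraderState",
    "RunResult",
    "Scorer",
    "score",
    "init_population",
    "largest_remainder_allocation",
    "update_group_sizes",
    "retailing",
    "distributing",
    "importing_exporting",
    "run_trader",
]

#: Sentinel ceiling for selections violating a hard adverse-reaction
#: constraint: an infeasible selection scores INFEASIBLE minus its number of
#: violating pairs.  Any feasible score beats any infeasible one, and among
#: infeasible selections fewer violations rank higher, so improvement-only
#: acceptance can climb out of an infeasible region (feasibility-first
#: ranking).  Finite (not -inf) so the property shifts in the group-size
#: reallocation stay well defined; scores <= INFEASIBLE never become the
#: incumbent.
INFEASIBLE = -1.0e9


class InvalidSelectionError(ValueError):
    """Raised when an all-zero selection reaches the score function."""


class CandidateSolution:
    """A binary selection vector with its trader group and score.

    The vector is stored as an integer bitmask (``mask``); ``variables``
    exposes the explicit 0/1 list.
    """

    __slots__ = ("mask", "m", "group", "score")

    def __init__(self, mask: int, m: int, group: int = 0, score: float = -math.inf):
        if mask < 0 or mask >> m:
            raise ValueError(f"mask {mask:#x} does not fit in {m} variables")
        self.mask = mask
        self.m = m
        self.group = group
        self.score = score

    @classmethod
    def from_variables(
        cls, variables: Sequence[int], group: int = 0, score: float = -math.inf
    ) -> "CandidateSolution":
        if any(v not in (0, 1) for v in variables):
            raise ValueError("variables must be binary")
        mask = 0
        for i, v in enumerate(variables):
            if v:
                mask |= 1 << i
        return cls(mask, len(variables), group, score)

    @property
    def variables(self) -> list[int]:
        return [(self.mask >> i) & 1 for i in range(self.m)]

    def selected_indices(self) -> list[int]:
        return [i for i in range(self.m) if (self.mask >> i) & 1]

    def copy(self) -> "CandidateSolution":
        return CandidateSolution(self.mask, self.m, self.group, self.score)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CandidateSolution({''.join(map(str, self.variables))}, g={self.group}, s={self.score:.4g})"


@dataclass(frozen=True)
class TraderConfig:
    """Algorithm parameters.

    population_size (C) and trader_count (T) default to 50 and 5; every group
    keeps at least min_members (M) = 2 solutions.  The stop condition is
    the evaluation budget, not an iteration count.
    """

    population_size: int = 50
    trader_count: int = 5
    min_members: int = 2
    max_evaluations: int = 10_000
    ddar_mode: str = "hard"  # "hard" or "penalty"
    penalty: float = 10.0  # per violating adverse pair, penalty mode only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trader_count < 2:
            raise ValueError("need at least two trader groups")
        if self.population_size < self.min_members * self.trader_count:
            raise ValueError("population smaller than M x T floor")
        if self.max_evaluations < self.population_size:
            raise ValueError("budget must cover the initial population scoring")
        if self.ddar_mode not in ("hard", "penalty"):
            raise ValueError(f"unknown ddar_mode {self.ddar_mode!r}")


class Scorer:
    """Shared scoring engine with evaluation accounting.

    Precomputes per-candidate coverage bitmasks (over the instance's main
    targets), side-effect counts and adverse-partner bitmasks.  Every
    optimizer in the package scores through one Scorer so that evaluation
    budgets are comparable; ``calls`` counts evaluations.
    """

    def __init__(self, dataset: CandidateDataset, cfg: TraderConfig | None = None):
        cfg = cfg or TraderConfig()
        self.dataset = dataset
        self.m = dataset.m
        target_bit = {t: i for i, t in enumerate(dataset.main_targets.targets())}
        self.coverage_masks = [
            sum(1 << target_bit[t] for t in c.covered) for c in dataset.candidates
        ]
        self.se = [float(c.se) for c in dataset.candidates]
        idx = {c.drug: i for i, c in enumerate(dataset.candidates)}
        self.adverse_masks = [0] * self.m
        for a, b in dataset.adverse_pairs:
            ia, ib = idx[a], idx[b]
            self.adverse_masks[ia] |= 1 << ib
            self.adverse_masks[ib] |= 1 << ia
        self.hard = cfg.ddar_mode == "hard"
        self.penalty = cfg.penalty
        self.calls = 0

    def score_mask(self, mask: int) -> float:
        """Score one selection bitmask; consumes one evaluation."""
        if mask == 0:
            raise InvalidSelectionError("all-zero selection; caller must repair")
        self.calls += 1
        cov = 0
        se_sum = 0.0
        k = 0
        violations = 0
        rem = mask
        adv = self.adverse_masks
        covm = self.coverage_masks
        se = self.se
        while rem:
            i = (rem & -rem).bit_length() - 1
            rem &= rem - 1
            violations += (adv[i] & mask).bit_count()
            cov |= covm[i]
            se_sum += se[i]
            k += 1
        violations //= 2  # each pair was seen from both ends
        if violations and self.hard:
            return INFEASIBLE - violations
        s = cov.bit_count() - se_sum / k
        if violations:
            s -= self.penalty * violations
        return s

    def feasible(self, mask: int) -> bool:
        rem = mask
        while rem:
            i = (rem & -rem).bit_length() - 1
            rem &= rem - 1
            if self.adverse_masks[i] & mask:
                return False
        return True


def score(cs: CandidateSolution, dataset: CandidateDataset, cfg: TraderConfig | None = None) -> float:
    """Score a solution against an instance (convenience, builds a Scorer)."""
    return Scorer(dataset, cfg).score_mask(cs.mask)


@dataclass
class TraderState:
    """Population, grouping and incumbent bookkeeping for one run."""

    population: list[CandidateSolution]
    groups: list[list[int]]  # per-group population indices
    scorer: Scorer
    cfg: TraderConfig
    rng: random.Random
    best_ever: CandidateSolution | None = None
    trace: list[float] = field(default_factory=list)

    @property
    def evaluations_used(self) -> int:
        return self.scorer.calls

    def properties(self) -> list[float]:
        """Per-trader property: the sum of its members' scores."""
        return [sum(self.population[i].score for i in g) for g in self.groups]

    def masters(self) -> list[int]:
        """Best member index per group; ties broken by lowest population index."""
        out = []
        for g in self.groups:
            out.append(max(sorted(g), key=lambda i: self.population[i].score))
        return out

    def consider(self, sol: CandidateSolution) -> None:
        """Update the incumbent; infeasible sentinels never become best_ever."""
        if sol.score <= INFEASIBLE:
            return
        if self.best_ever is None or sol.score > self.best_ever.score:
            self.best_ever = sol.copy()

    def budget_left(self) -> bool:
        return self.scorer.calls < self.cfg.max_evaluations


@dataclass
class RunResult:
    """Outcome of one optimizer run on one instance."""

    selected: list[str]
    variables: list[int]
    objective: float  # reported, negated score: lower is better
    trace: list[float]  # reported best objective per iteration
    evaluations_used: int
    feasible: bool
    algorithm: str = "trader"


def _repair_zero(mask: int, m: int, rng: random.Random) -> int:
    """All-zero selections are undefined (score divides by the selection
    size); set one uniformly random bit instead of scoring them."""
    return mask if mask else 1 << rng.randrange(m)


def init_population(
    m: int, cfg: TraderConfig, dataset: CandidateDataset, rng: random.Random | None = None
) -> TraderState:
    """Random initial population: i.i.d. Bernoulli(0.5) bits, zero vectors
    repaired, groups assigned round-robin (equal sizes up to one), everything
    scored (consumes C evaluations)."""
    if m < 1:
        raise ValueError("need at least one candidate")
    rng = rng or random.Random(cfg.seed)
    scorer = Scorer(dataset, cfg)
    if scorer.m != m:
        raise ValueError("length disagrees with the instance")
    state = TraderState([], [[] for _ in range(cfg.trader_count)], scorer, cfg, rng)
    for i in range(cfg.population_size):
        mask = _repair_zero(rng.getrandbits(m), m, rng)
        g = i % cfg.trader_count
        sol = CandidateSolution(mask, m, group=g)
        sol.score = scorer.score_mask(mask)
        state.population.append(sol)
        state.groups[g].append(i)
        state.consider(sol)
    return state


def largest_remainder_allocation(weights: Sequence[float], pool: int) -> list[int]:
    """Split ``pool`` integer slots proportionally to nonnegative weights.

    Floors the proportional shares, then hands the remaining slots to the
    largest fractional remainders (ties to the lower index), so the result
    sums exactly to ``pool``.
    """
    total = sum(weights)
    if total <= 0:
        raise ValueError("weights must have positive sum")
    raw = [w / total * pool for w in weights]
    shares = [int(r) for r in raw]
    short = pool - sum(shares)
    order = sorted(range(len(weights)), key=lambda i: (-(raw[i] - shares[i]), i))
    for i in order[:short]:
        shares[i] += 1
    return shares


def update_group_sizes(state: TraderState, cfg: TraderConfig) -> list[int]:
    """Reallocate members to groups in proportion to trader properties.

    Each group gets M base members plus a share of the C - M*T pool
    proportional to its positive-shifted property (shift by -min + 1 so
    negative properties cannot break the allocation), rounded by largest
    remainder so the counts sum exactly to C.  Members then migrate
    worst-first from shrinking to growing groups; masters stay put.
    Returns the new per-group member counts.
    """
    props = state.properties()
    pool = cfg.population_size - cfg.min_members * cfg.trader_count
    shift = -min(props) + 1.0
    shares = largest_remainder_allocation([p + shift for p in props], pool)
    targets = [cfg.min_members + s for s in shares]

    masters = set(state.masters())
    pool_members: list[int] = []
    for gi, g in enumerate(state.groups):
        excess = len(g) - targets[gi]
        if excess <= 0:
            continue
        movable = sorted(
            (i for i in g if i not in masters),
            key=lambda i: (state.population[i].score, i),
        )
        for i in movable[:excess]:
            g.remove(i)
            pool_members.append(i)
    pool_members.sort(key=lambda i: (state.population[i].score, i))
    for gi, g in enumerate(state.groups):
        while len(g) < targets[gi]:
            i = pool_members.pop(0)
            g.append(i)
            state.population[i].group = gi
    assert not pool_members
    return targets


def _try_accept(
    sol: CandidateSolution, trial_mask: int, state: TraderState
) -> bool:
    """Score a trial mask and keep it only on strict improvement."""
    s = state.scorer.score_mask(trial_mask)
    if s > sol.score:
        sol.mask, sol.score = trial_mask, s
        state.consider(sol)
        return True
    return False


def retailing(
    slave: CandidateSolution, state: TraderState, rng: random.Random | None = None
) -> bool:
    """Flip a small random set of the slave's bits (minimum change operator).

    R is uniform in [1, ceil(m/10)] (floor 1 for short vectors); positions
    are distinct and each flip is V(K) <- |V(K) - 1|.  Improvement-only:
    a non-improving trial is discarded and the previous variables kept.
    Consumes one evaluation; returns True if the change was accepted.
    """
    rng = rng or state.rng
    m = slave.m
    r_max = max(1, math.ceil(m / 10))
    r = rng.randint(1, r_max)
    trial = slave.mask
    for k in rng.sample(range(m), r):
        trial ^= 1 << k
    trial = _repair_zero(trial, m, rng)
    return _try_accept(slave, trial, state)


def _copy_positions(
    src_mask: int, dst_mask: int, m: int, rng: random.Random
) -> int:
    """Copy R random distinct positions (R uniform in [1, m]) from src to dst."""
    r = rng.randint(1, m)
    trial = dst_mask
    for k in rng.sample(range(m), r):
        bit = 1 << k
        trial = (trial | bit) if (src_mask & bit) else (trial & ~bit)
    return trial


def distributing(
    master: CandidateSolution,
    slave: CandidateSolution,
    state: TraderState,
    rng: random.Random | None = None,
) -> bool:
    """Copy a random set of positions from the group's master to a slave.

    Improvement-only acceptance; consumes one evaluation.
    """
    if master.group != slave.group:
        raise ValueError("distributing requires a master and slave of one group")
    rng = rng or state.rng
    trial = _copy_positions(master.mask, slave.mask, slave.m, rng)
    trial = _repair_zero(trial, slave.m, rng)
    return _try_accept(slave, trial, state)


def importing_exporting(
    importer: CandidateSolution,
    exporter: CandidateSolution,
    state: TraderState,
    rng: random.Random | None = None,
) -> bool:
    """Copy a random set of positions from the exporter master into the
    importer master (the only operator that changes masters).

    The masters must belong to distinct groups.  Improvement-only; one
    evaluation.
    """
    if importer.group == exporter.group:
        raise ValueError("importer and exporter must be masters of distinct groups")
    rng = rng or state.rng
    trial = _copy_positions(exporter.mask, importer.mask, importer.m, rng)
    trial = _repair_zero(trial, importer.m, rng)
    return _try_accept(importer, trial, state)


def run_trader(dataset: CandidateDataset, cfg: TraderConfig | None = None) -> RunResult:
    """Run the Trader optimizer on one instance under an evaluation budget.

    Per iteration: each group's master distributes to every slave, every
    slave retails, one importing-exporting event fires (importer drawn
    uniformly among masters, exporter from the remaining masters with
    probability proportional to positive-shifted trader property -- richer
    traders export), then group sizes are reallocated.  The loop stops as
    soon as the budget is exhausted, mid-iteration if necessary.
    """
    cfg = cfg or TraderConfig()
    rng = random.Random(cfg.seed)
    state = init_population(dataset.m, cfg, dataset, rng)

    while state.budget_left():
        masters = state.masters()
        master_set = set(masters)
        for gi, g in enumerate(state.groups):
            master = state.population[masters[gi]]
            for i in g:
                if i in master_set:
                    continue
                slave = state.population[i]
                if not state.budget_left():
                    break
                distributing(master, slave, state, rng)
                if not state.budget_left():
                    break
                retailing(slave, state, rng)
            if not state.budget_left():
                break

        if state.budget_left() and len(masters) >= 2:
            imp_pos = rng.randrange(len(masters))
            others = [gi for gi in range(len(masters)) if gi != imp_pos]
            props = state.properties()
            shift = -min(props[gi] for gi in others) + 1.0
            weights = [props[gi] + shift for gi in others]
            exp_pos = rng.choices(others, weights=weights, k=1)[0]
            importing_exporting(
                state.population[masters[imp_pos]],
                state.population[masters[exp_pos]],
                state,
                rng,
            )

        update_group_sizes(state, cfg)
        state.trace.append(
            math.nan if state.best_ever is None else state.best_ever.score
        )

    best = state.best_ever
    if best is None:
        # every scored selection violated the hard adverse constraint
        best = max(state.population, key=lambda s: s.score)
        feasible = False
        objective = math.inf
    else:
        feasible = True
        objective = -best.score
    names = dataset.drug_names
    return RunResult(
        selected=[names[i] for i in best.selected_indices()],
        variables=best.variables,
        objective=objective,
        trace=[-s for s in state.trace],
        evaluations_used=state.scorer.calls,
        feasible=feasible,
        algorithm="trader",
    )
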