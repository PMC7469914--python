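"""Exact oracle and generic stochastic baselines.

The exhaustive oracle enumerates every nonempty selection of an instance
(vectorized, practical up to 20 candidates) and returns the global optimum
under the same objective and adverse-reaction semantics as the Trader
optimizer.  It anchors property-based testing: no stochastic optimizer may
ever report an objective better than the oracle's.

``random_search`` and ``hill_climb`` are deliberately generic reference
optimizers used to exercise the benchmark statistics; they score through the
shared :class:`~drugtrader.trader_core.Scorer`, so evaluation budgets are
directly comparable with Trader's.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np

from .interaction_store import CandidateDataset
from .trader_core import INFEASIBLE, RunResult, Scorer, TraderConfig, _repair_zero

__all__ = ["OracleResult", "exhaustive_oracle", "random_search", "hill_climb"]

_ORACLE_MAX_M = 20


@dataclass(frozen=True)
class OracleResult:
    """Global optimum of one instance by complete enumeration."""

    optimal_selection: tuple[int, ...]  # binary vector
    optimal_objective: float  # reported scale (negated score, lower better)
    enumerated: int  # feasible nonempty selections evaluated
    n_optima: int  # selections attaining the optimum (ties)


def exhaustive_oracle(dataset: CandidateDataset, cfg: TraderConfig | None = None) -> OracleResult:
    """Enumerate all nonempty selections and return the best.

    Applies the identical objective as the Trader scorer (coverage minus
    mean side-effect load; hard adverse pairs excluded, or penalized in
    penalty mode).  Deterministic; ties resolved toward the lowest selection
    bitmask.  Guarded to m <= 20.
    """
    cfg = cfg or TraderConfig()
    m = dataset.m
    if m > _ORACLE_MAX_M:
        raise ValueError(f"oracle guard: m={m} exceeds {_ORACLE_MAX_M}")

    n_sel = (1 << m) - 1
    masks = np.arange(1, 1 << m, dtype=np.int64)
    sel = ((masks[:, None] >> np.arange(m)) & 1).astype(bool)  # (2^m-1, m)

    target_order = dataset.main_targets.targets()
    tpos = {t: i for i, t in enumerate(target_order)}
    covbool = np.zeros((m, len(target_order)), dtype=bool)
    se = np.zeros(m)
    for i, c in enumerate(dataset.candidates):
        for t in c.covered:
            covbool[i, tpos[t]] = True
        se[i] = c.se

    at = (sel @ covbool.astype(np.int64) > 0).sum(axis=1)
    k = sel.sum(axis=1)
    scores = at - (sel @ se) / k

    idx = {c.drug: i for i, c in enumerate(dataset.candidates)}
    violations = np.zeros(n_sel, dtype=np.int64)
    for a, b in dataset.adverse_pairs:
        violations += sel[:, idx[a]] & sel[:, idx[b]]
    if cfg.ddar_mode == "hard":
        feasible = violations == 0
        scores = np.where(feasible, scores, INFEASIBLE - violations)
        enumerated = int(feasible.sum())
    else:
        scores = scores - cfg.penalty * violations
        enumerated = n_sel

    best = float(scores.max())
    if best <= INFEASIBLE:
        raise ValueError("instance has no feasible nonempty selection")
    optima = np.flatnonzero(scores == best)
    best_mask = int(masks[optima[0]])
    selection = tuple((best_mask >> i) & 1 for i in range(m))
    return OracleResult(
        optimal_selection=selection,
        optimal_objective=-best,
        enumerated=enumerated,
        n_optima=int(optima.size),
    )


def _finish(
    scorer: Scorer,
    dataset: CandidateDataset,
    best_mask: int,
    best_score: float,
    trace: list[float],
    algorithm: str,
) -> RunResult:
    names = dataset.drug_names
    feasible = best_score > INFEASIBLE
    return RunResult(
        selected=[names[i] for i in range(dataset.m) if (best_mask >> i) & 1],
        variables=[(best_mask >> i) & 1 for i in range(dataset.m)],
        objective=-best_score if feasible else math.inf,
        trace=trace,
        evaluations_used=scorer.calls,
        feasible=feasible,
        algorithm=algorithm,
    )


def random_search(
    dataset: CandidateDataset,
    budget: int,
    seed: int = 0,
    cfg: TraderConfig | None = None,
    trace_every: int = 100,
) -> RunResult:
    """Sample i.i.d. Bernoulli(0.5) selections and keep the best seen."""
    if budget < 1:
        raise ValueError("budget must be positive")
    rng = random.Random(seed)
    scorer = Scorer(dataset, cfg)
    m = dataset.m
    best_mask, best_score = 0, -math.inf
    trace: list[float] = []
    while scorer.calls < budget:
        mask = _repair_zero(rng.getrandbits(m), m, rng)
        s = scorer.score_mask(mask)
        if s > best_score and s > INFEASIBLE:
            best_mask, best_score = mask, s
        if scorer.calls % trace_every == 0:
            trace.append(-best_score)
    return _finish(scorer, dataset, best_mask, best_score, trace, "random")


def hill_climb(
    dataset: CandidateDataset,
    budget: int,
    seed: int = 0,
    cfg: TraderConfig | None = None,
    trace_every: int = 100,
) -> RunResult:
    """First-improvement single-bit-flip local search with random restarts."""
    if budget < 1:
        raise ValueError("budget must be positive")
    rng = random.Random(seed)
    scorer = Scorer(dataset, cfg)
    m = dataset.m
    best_mask, best_score = 0, -math.inf
    trace: list[float] = []

    def note(mask: int, s: float) -> None:
        nonlocal best_mask, best_score
        if s > best_score and s > INFEASIBLE:
            best_mask, best_score = mask, s
        if scorer.calls % trace_every == 0:
            trace.append(-best_score)

    while scorer.calls < budget:
        cur = _repair_zero(rng.getrandbits(m), m, rng)
        cur_score = scorer.score_mask(cur)
        note(cur, cur_score)
        improved = True
        while improved and scorer.calls < budget:
            improved = False
            for k in rng.sample(range(m), m):
                if scorer.calls >= budget:
                    break
                trial = cur ^ (1 << k)
                if trial == 0:
                    continue
                s = scorer.score_mask(trial)
                note(trial, s)
                if s > cur_score:
                    cur, cur_score = trial, s
                    improved = True
                    break
        # local optimum reached: random restart
    return _finish(scorer, dataset, best_mask, best_score, trace, "hillclimb")
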