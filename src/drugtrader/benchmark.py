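"""Repeated-run evaluation protocol: statistics, hypothesis tests, TSV reports.

Stochastic optimizers are compared by executing each one many times (50 by
default) per instance under the same evaluation budget and summarizing the
reported objectives (lower is better): worst, best, mean, sample standard
deviation and a two-sided 95% t-interval on the mean.  Two kinds of
hypothesis test accompany the summaries:

* a per-algorithm "chance" p-value: a two-sided rank-sum test of the
  algorithm's objectives against equal-budget random-search objectives on
  the same instance, quantifying how distinguishable its behavior is from
  blind sampling;
* pairwise one-sided Wilcoxon rank-sum tests of a designated base algorithm
  against each competitor, with H0 "the base performs the same" rejected in
  favor of H1 "the base is more efficient" when p < 0.05.

Convergence (mean best objective per iteration) and stability (final
objective per run) traces are exported alongside the tables as TSV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import hill_climb, random_search
from .interaction_store import CandidateDataset
from .trader_core import RunResult, TraderConfig, run_trader

__all__ = [
    "ALGORITHMS",
    "BenchmarkReport",
    "wilcoxon_compare",
    "summary_stats",
    "run_benchmark",
    "derive_seed",
]

ALPHA = 0.05

logger = logging.getLogger(__name__)


def _run_trader(ds: CandidateDataset, budget: int, seed: int, cfg: TraderConfig) -> RunResult:
    return run_trader(ds, replace(cfg, max_evaluations=budget, seed=seed))


def _run_random(ds: CandidateDataset, budget: int, seed: int, cfg: TraderConfig) -> RunResult:
    return random_search(ds, budget, seed, cfg)


def _run_hillclimb(ds: CandidateDataset, budget: int, seed: int, cfg: TraderConfig) -> RunResult:
    return hill_climb(ds, budget, seed, cfg)


ALGORITHMS: dict[str, Callable[[CandidateDataset, int, int, TraderConfig], RunResult]] = {
    "trader": _run_trader,
    "random": _run_random,
    "hillclimb": _run_hillclimb,
}


def derive_seed(seed_base: int, algorithm: str, instance: str, run: int) -> int:
    """Stable per-run seed below 2^31, independent across algorithm streams."""
    h = 17
    for token in (algorithm, instance):
        for ch in token:
            h = (h * 31 + ord(ch)) % (1 << 31)
    return (seed_base * 1_000_003 + h * 10_007 + run) % (1 << 31)


def wilcoxon_compare(
    base_scores: Sequence[float],
    other_scores: Sequence[float],
    alpha: float = ALPHA,
) -> tuple[float, str]:
    """One-sided Wilcoxon rank-sum: is the base algorithm more efficient?

    Objectives are on the lower-is-better scale, so "more efficient" means
    the base's scores tend to be smaller (alternative "less").  Returns the
    p-value and the decision: "H1" (base more efficient) when p < alpha,
    otherwise "H0" (same performance).  The exact null distribution is used
    for small tie-free samples, the tie-corrected normal approximation
    otherwise; two identical constant samples yield p = 1.0 with a warning.
    """
    base = np.asarray(base_scores, dtype=float)
    other = np.asarray(other_scores, dtype=float)
    if base.size < 2 or other.size < 2:
        raise ValueError("both samples need at least two observations")
    pooled = np.concatenate([base, other])
    if np.ptp(pooled) == 0.0:
        warnings.warn("constant identical samples; rank-sum test degenerate", stacklevel=2)
        return 1.0, "H0"
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (base.size <= 25 and other.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(base, other, alternative="less", method=method)
    p = float(res.pvalue)
    return p, ("H1" if p < alpha else "H0")


def summary_stats(scores: Sequence[float], confidence: float = 0.95) -> dict[str, float]:
    """Worst/best/mean/sample-SD and a two-sided t-interval on the mean.

    On the reported lower-is-better scale the worst run is the largest
    objective and the best the smallest.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two runs to summarize")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        lo = hi = mean
    else:
        lo, hi = stats.t.interval(confidence, df=x.size - 1, loc=mean, scale=stats.sem(x))
    return {
        "worst": float(x.max()),
        "best": float(x.min()),
        "mean": mean,
        "std": sd,
        "ci_low": float(lo),
        "ci_high": float(hi),
    }


@dataclass
class BenchmarkReport:
    """All raw and derived benchmark outputs; regenerable from ``raw``."""

    raw: pd.DataFrame  # instance, algorithm, run, seed, objective, evaluations
    stats: pd.DataFrame  # per (instance, algorithm) summary + p_chance
    pairwise: pd.DataFrame  # base vs other one-sided Wilcoxon
    convergence: pd.DataFrame  # instance, algorithm, iteration, mean_objective
    n_runs: int
    budget: int
    base_algorithm: str

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = dict(sep="\t", index=False, float_format="%.6g")
        self.stats.to_csv(outdir / "table2.tsv", **fmt)
        self.pairwise.to_csv(outdir / "table4.tsv", **fmt)
        self.convergence.to_csv(outdir / "convergence.tsv", **fmt)
        stability = self.raw[["instance", "algorithm", "run", "objective"]]
        stability.to_csv(outdir / "stability.tsv", **fmt)
        self.raw.to_csv(outdir / "raw_scores.tsv", **fmt)


def _mean_convergence(traces: list[list[float]]) -> list[float]:
    n = min(len(t) for t in traces)
    if n == 0:
        return []
    arr = np.array([t[:n] for t in traces], dtype=float)
    return arr.mean(axis=0).tolist()


def run_benchmark(
    instances: Mapping[str, CandidateDataset],
    algorithms: Sequence[str] = ("trader", "random", "hillclimb"),
    n_runs: int = 50,
    budget: int = 10_000,
    seed_base: int = 0,
    cfg: TraderConfig | None = None,
    base_algorithm: str = "trader",
) -> BenchmarkReport:
    """Run every algorithm ``n_runs`` times per instance and aggregate.

    Every algorithm receives the same evaluation budget; per-run seeds are
    derived deterministically from ``seed_base`` with independent streams
    per (algorithm, instance).  Random-search objectives are always
    computed (even when not among the requested algorithms) because they
    anchor the per-algorithm chance p-value.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be at least 2")
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")
    if base_algorithm not in algorithms:
        raise ValueError("base_algorithm must be among the requested algorithms")
    cfg = cfg or TraderConfig()

    rows = []
    conv_rows = []
    objectives: dict[tuple[str, str], list[float]] = {}
    for inst_name, dataset in instances.items():
        needed = list(dict.fromkeys([*algorithms, "random"]))
        for algo in needed:
            runner = ALGORITHMS[algo]
            traces = []
            for run in range(n_runs):
                seed = derive_seed(seed_base, algo, inst_name, run)
                result = runner(dataset, budget, seed, cfg)
                objectives.setdefault((inst_name, algo), []).append(result.objective)
                traces.append(result.trace)
                logger.info(
                    "run instance=%s algorithm=%s run=%d seed=%d evaluations=%d objective=%.6g",
                    inst_name, algo, run, seed, result.evaluations_used, result.objective,
                )
                if algo in algorithms:
                    rows.append(
                        {
                            "instance": inst_name,
                            "algorithm": algo,
                            "run": run,
                            "seed": seed,
                            "objective": result.objective,
                            "evaluations": result.evaluations_used,
                        }
                    )
            if algo in algorithms:
                for it, val in enumerate(_mean_convergence(traces)):
                    conv_rows.append(
                        {
                            "instance": inst_name,
                            "algorithm": algo,
                            "iteration": it,
                            "mean_objective": val,
                        }
                    )

    raw = pd.DataFrame(rows)
    stat_rows = []
    pair_rows = []
    for inst_name in instances:
        chance = objectives[(inst_name, "random")]
        for algo in algorithms:
            scores = objectives[(inst_name, algo)]
            entry = {"instance": inst_name, "algorithm": algo, **summary_stats(scores)}
            pooled = np.concatenate([scores, chance])
            if np.ptp(pooled) == 0.0:
                entry["p_chance"] = 1.0
            else:
                entry["p_chance"] = float(
                    stats.mannwhitneyu(
                        scores, chance, alternative="two-sided", method="asymptotic"
                    ).pvalue
                )
            stat_rows.append(entry)
            if algo != base_algorithm:
                p, decision = wilcoxon_compare(objectives[(inst_name, base_algorithm)], scores)
                pair_rows.append(
                    {
                        "instance": inst_name,
                        "base": base_algorithm,
                        "algorithm": algo,
                        "p_value": p,
                        "decision": decision,
                    }
                )

    return BenchmarkReport(
        raw=raw,
        stats=pd.DataFrame(stat_rows),
        pairwise=pd.DataFrame(pair_rows),
        convergence=pd.DataFrame(conv_rows),
        n_runs=n_runs,
        budget=budget,
        base_algorithm=base_algorithm,
    )
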