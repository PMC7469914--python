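# drugtrader

Synthetic drug repurposing: replacing a single drug with a *combination* of
other approved drugs that jointly cover its disease-relevant targets,
ideally with fewer total side effects. This is the substitution problem
(use A + B *instead of* C), distinct from combination therapy (add E *to*
C). The package implements a two-step pipeline for it, developed around
hypertension as the driving disease:

1. **Rule mining.** From drug–disease, drug–target and target–target
   relations, five deterministic If–Then rules admit candidate drugs: a
   drug qualifies if it acts on a disease-inducing target with exactly the
   required effect (inhibit / induce / agonize / antagonize), or acts on an
   enzyme or protein one relation hop away from such a target with the
   required effect. Effect matching is strict — an agonist of a receptor is
   *not* a substitute where an antagonist is required.

2. **Combination selection.** The **Trader** discrete optimizer searches
   binary selection vectors `V ∈ {0,1}^m` over the `m` candidates,
   maximizing

   ```
   score(V) = AT − (Σ_i V_i · SE_i) / (Σ_i V_i)
   ```

   where `AT` is the number of distinct main targets jointly covered and
   `SE_i` is candidate *i*'s side-effect count (its interactions beyond the
   main targets). Reports negate the score, so printed objectives follow
   the lower-is-better convention (a perfect one-target, zero-side-effect
   substitute prints −1.0). Selections containing a known adverse drug–drug
   pair are infeasible (hard constraint; a soft penalty mode exists).

   Trader maintains a population of solutions partitioned into trader
   groups, each with a master (best) solution. Per iteration: masters
   *distribute* values to their slaves, slaves *retail* (flip a few bits),
   one master *imports* values from another, all under improvement-only
   acceptance; group sizes are then reallocated proportionally to each
   trader's property (the sum of its members' scores) with a two-member
   floor, so no trader is ever eliminated. Termination is a fixed budget of
   score-function evaluations, which keeps comparisons with other
   optimizers fair.

The package also ships an exhaustive oracle and generic baselines
(random search, hill climbing), a weighted chemical-formula similarity
score for inspecting proposed substitutes, a synthetic-instance generator
with presets matching the published instance shapes (real inputs come from
curated pharmacology databases and are not redistributable), and a
benchmarking harness (repeated seeded runs, Wilcoxon rank-sum tests,
convergence/stability traces).

## Worked example

```python
from drugtrader import (
    GeneratorSpec, TraderConfig, exhaustive_oracle, generate, run_trader,
)

ds = generate(GeneratorSpec(n_candidates=12, n_main_targets=4, seed=3))
print(exhaustive_oracle(ds).optimal_objective)
res = run_trader(ds, TraderConfig(max_evaluations=5000, seed=1))
print(res.objective, res.selected)
```

prints

```
-3.0
-3.0 ['D004', 'D011']
```

The oracle enumerates all 2¹² − 1 selections of this 12-candidate,
4-target instance: the best possible objective is −3.0 (e.g. four covered
targets at an average side-effect load of 1). Trader reaches the same
objective within its 5,000-evaluation budget, selecting two drugs that
jointly cover the main targets.

The same pipeline is scriptable from the shell:

```sh
drugtrader mine --disease HT --matrices data/ --out candidates.tsv
drugtrader optimize --instance instance.json --seed 1 --out result.json
drugtrader similarity --formulas formulas.tsv --pairs pairs.tsv --out sims.tsv
drugtrader benchmark --preset NIC --runs 50 --budget 10000 --seed-base 1 --out report/
```

## Layout

| Module | Role |
| --- | --- |
| `interaction_store` | relational matrices, TSV I/O, instance construction |
| `rule_miner` | disease target derivation and the five admission rules |
| `trader_core` | the Trader optimizer (scoring, operators, group economy) |
| `baselines` | exhaustive oracle, random search, hill climbing |
| `similarity` | formula parsing and weighted drug–drug similarity |
| `synthetic_data` | instance generator, presets, planted optima |
| `benchmark` | repeated-run statistics, Wilcoxon tests, TSV reports |
| `cli` | `drugtrader` command-line entry points |

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
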