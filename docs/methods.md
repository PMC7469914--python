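# Methods

## Problem

Given a drug prescribed for a disease, find a small set of other approved
drugs that jointly covers the disease-relevant ("main") targets of the
given drug with the correct mechanism of action on each, while minimizing
the average side-effect load of the set and avoiding known adverse
drug–drug pairs. The deliverable of the pipeline is a ranked substitution
list per given drug.

## Data model

Four sparse relations carry the pharmacology: a binary drug–disease
indication matrix; a drug–target matrix whose cells are effect labels
(INH, IND, AGO, ANT — absence encodes no interaction); a symmetric binary
drug–drug adverse-reaction matrix; and directed target–target relations,
each endpoint classed as enzyme or protein and carrying an effect label.
Identifiers are opaque case-sensitive strings; files are tab-separated
with one relation per row and a required header, chosen as the simplest
lossless carrier for sparse relations. Unknown effect tokens reject with
the offending line rather than coerce.

## Rule mining

The disease target set contains (target, required-effect) pairs: every
target touched by a drug indicated for the disease, with the effect of
that interaction. When two indicated drugs act on one target with
different effects, both pairs are retained and the conflict is logged —
the data cannot adjudicate which mechanism matters, and dropping either
would silently shrink the candidate pool. (Target uniqueness is therefore
enforced on (target, effect) pairs, not targets alone.)

Admission is by five deterministic implications: a direct hit on a disease
target with exactly the required effect, or a hit on an enzyme/protein
whose one-hop relation into a disease protein/enzyme carries the required
effect (four class combinations). Chaining depth is exactly one relation
hop — the rule set enumerates two-entity rules only, and transitive
closure would change the semantics from stated implications to reachability.
Effect equality is strict label equality with no aliasing: an agonist is
not admitted where an antagonist is required, even on the same receptor,
because it would aggravate rather than counter the disease. Each admission
carries a trace (rule id, hop path) that tests re-verify independently.

A curated (target, effect) file can substitute for matrix derivation, since
disease target sets are often literature-curated rather than derived.

## Scoring and constraints

A candidate solution is a binary vector over the m candidates. Its score,
maximized internally, is

    score(V) = AT − (Σ V_i · SE_i) / (Σ V_i)

with AT the number of *distinct* main targets covered by the selection
(union semantics — covering one target twice confers no extra credit; the
alternative sum-with-multiplicity reading would reward redundant
combinations) and SE_i the candidate's side-effect count (its total
interactions minus its covered main targets). All reports negate the
score so that smaller printed objectives are better; a one-target,
zero-side-effect substitute reports −1.0.

All-zero selections are undefined (the score divides by the selection
size); wherever an operator or initializer produces one, a single
uniformly random bit is set instead of scoring it.

Adverse pairs are handled in one of two modes:

* **hard** (default): an infeasible selection scores
  `INFEASIBLE − (number of violating pairs)` with `INFEASIBLE = −1e9`.
  Any feasible score beats any infeasible one and scores at or below the
  sentinel never become the incumbent, so reported solutions are always
  feasible. Grading the sentinel by violation count (feasibility-first
  ranking) matters on larger instances: a Bernoulli(0.5) initial
  population selects about m/2 drugs and is then almost surely entirely
  infeasible, and under a flat sentinel the improvement-only operators
  would have no gradient by which to escape.
* **penalty**: the score is reduced by λ per violating pair (default
  λ = 10, large enough to dominate any single-target gain on the instance
  scales shipped here). Useful when adverse data are noisy and a
  near-miss list is wanted.

## The Trader optimizer

Population of C solutions in T trader groups, each group holding a master
(its best member; ties to the lowest population index) and slaves. A
trader's property is the sum of its members' scores. Per iteration:

1. **distributing** — each group's master copies R positions (R uniform in
   [1, m], distinct positions) onto each slave;
2. **retailing** — each slave flips R distinct bits, R uniform in
   [1, ceil(m/10)] with a floor of one flip;
3. **importing–exporting** — one event per iteration: an importer master
   chosen uniformly, an exporter drawn from the remaining masters with
   probability proportional to positive-shifted property (richer traders
   export), R positions copied exporter → importer;
4. **regrouping** — every group keeps a floor of M = 2 members; the
   remaining C − M·T slots are shared proportionally to properties shifted
   by (−min + 1) (so negative properties cannot break the allocation),
   with largest-remainder rounding forcing the exact sum C (remainder ties
   to the lower group index). Members migrate worst-first from shrinking
   to growing groups; masters never migrate, so no group loses its best
   solution and none is eliminated.

All three operators are improvement-only: the trial is re-scored (one
evaluation) and kept only on strict improvement, otherwise the previous
variables are restored. Whether distributing touches every slave or a
sample each iteration is underdetermined; every slave is used, which makes
one iteration cost 2(C − T) + 1 evaluations.

Termination is a fixed evaluation budget, checked before every single
evaluation so a run never overshoots it; budget-based stopping (rather
than iteration counts) is what makes cross-optimizer comparisons fair.
Defaults: C = 50, T = 5, 10,000 evaluations.

Selections are stored as integer bitmasks; scoring walks the set bits with
precomputed per-candidate coverage and adverse-partner masks. This keeps a
single evaluation at a few microseconds, which the repeated-run protocols
below rely on.

## Oracle and baselines

The exhaustive oracle enumerates all nonempty selections (vectorized,
guarded to m ≤ 20), applies the identical objective, and returns the
global optimum plus the number of optima (uniqueness matters for
exact-recovery tests). Random search (i.i.d. Bernoulli(0.5) selections)
and first-improvement hill climbing with random restarts serve as generic
reference optimizers; published comparison algorithms from other work are
deliberately not replicated — the benchmark harness only needs score
distributions to exercise its statistics. All optimizers score through one
shared scorer with evaluation accounting.

## Synthetic instances

The generator emulates the structure the optimizer sees: candidate count,
main-target count, per-candidate coverage subsets, side-effect counts, and
adverse-pair density. Defaults, chosen once as field-plausible values:

* `se_rate = 3` — Poisson mean of side-effect counts; the study drugs'
  own residual-target counts span 0–11 with typical values of a few;
* `coverage_p = 0.5` — truncated-geometric law of covered-subset sizes;
  most drugs hit a single main target, larger covered sets are
  exponentially rarer;
* `ddar_density = 0.05` — adverse interactions are sparse among drugs
  already filtered to act on a common disease.

Named presets reproduce the nine published instance shapes (total targets,
main targets, candidate-pool size), e.g. Nicardipine 15/4/40; three
presets whose published shape digits are ambiguous are read as 1/1/16,
2/1/26 and 2/2/28, consistent with the ascending candidate-count ordering.
Per-candidate side-effect values are synthetic throughout because real
per-drug counts were never published — so passing tests establish the
correctness and reliability of the machinery on instances of realistic
shape, not pharmacological validity of any particular substitution list.
The generator does not model correlated coverage (drug families), degree
structure in the adverse graph, or heavy-tailed side-effect counts.

`plant_optimum` constructs instances whose global optimum is known: k
designated drugs partition the main targets (each covering a nonempty
block) at zero side effects, every other drug carries at least one, and
no adverse pair lies inside the planted set. The planted selection is
then the strict unique optimum, re-verified by the oracle (including
uniqueness) before the instance is released.

## Benchmark statistics

Each optimizer runs 50 times per instance (repeated seeded runs; per-run
seeds derive deterministically from a base seed with independent streams
per algorithm × instance) under equal budgets. Summaries: worst, best,
mean, sample SD, and a two-sided 95% t-interval on the mean. Two tests:

* per-algorithm "chance" p-value: two-sided rank-sum of the algorithm's
  objectives against equal-budget random-search objectives on the same
  instance;
* pairwise one-sided Wilcoxon rank-sum of a base algorithm vs each
  competitor; H0 ("same performance") is rejected for H1 ("base more
  efficient") when p < 0.05. The exact null distribution is used for
  tie-free samples of at most 25 each, the tie-corrected normal
  approximation otherwise; identical constant samples return p = 1.0 with
  a warning rather than a degenerate statistic.

Convergence (mean best objective per iteration, truncated to the shortest
run) and stability (final objective per run) export as TSV; plotting is
left to the consumer.

## Verification scale

The acceptance-level checks run on one CPU in a few minutes total:
oracle-equivalence on thirty instances of 12–15 candidates (50 runs × 
5,000 evaluations each, against exhaustive enumeration), planted-optimum
recovery at k ∈ {1,2,3} × n ∈ {10,15,20}, a thousand brute-force score
recomputations, 200 Wilcoxon self-comparisons for type-I calibration, and
500 random formula vectors for the similarity properties. Candidate
counts of 12–15 for the oracle-equivalence sweep sit deliberately where
blind random sampling at the same budget starts failing (its per-run hit
probability is roughly 1 − (1 − 2^−m)^budget for a unique optimum), so
the comparison against it is informative.

## Formula similarity

Formulas are element-count vectors parsed from Hill notation (underscore
and Unicode subscripts tolerated; implicit count 1; unknown element
tokens reject with their position). The pair weight

    w_r = min(d_r, 1) · min(C_i,r, C_j,r) / (max(C_i,r, C_j,r) + eps)

uses eps = 1e−12 and a corpus frequency d_r, defined as the fraction of
corpus drugs containing element r (this makes the min(d_r, 1) clamp
meaningful; without a corpus d_r defaults to 1). Two modes ship because
the literal ratio form Σ(w·C_i·C_j) / Σ(w·√(C_i·C_j)) is unbounded and
does not reproduce the historically printed similarity values for the
published drug pairs on their printed formulas (those values are treated
as non-binding); the normalized cosine form
Σ(w·C_i·C_j) / √(Σ w·C_i² · Σ w·C_j²) is bounded in [0, 1] and is the
reporting default.

One caveat follows from the weighting: because w_r absorbs the count
ratio, the normalized score equals 1 exactly when the two count vectors
are proportional — element *proportions*, not absolute counts, are what
is compared. A corollary is that adding a shared equal-count element can
lower the score of a non-proportional pair; monotonicity in shared
components holds only through the proportionality structure.

## Known limitations

* Element-count similarity ignores structure; two isomers score 1.0.
  Structural fingerprints are out of scope by design.
* The rule miner's one-hop relation semantics cannot express cascades;
  this is faithful to the stated rule set, not a modeling claim.
* Under hard constraints on instances whose feasible region is a sparse
  independent set of the adverse graph, the optimizer's initial
  population may be entirely infeasible; the graded sentinel recovers in
  practice, but pathological adverse graphs (near-complete) would leave
  only singletons feasible and the search degenerates to scanning them.
* Reported instances are synthetic; no claim about real substitution
  lists is made or tested.
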