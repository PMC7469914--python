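"""Synthetic optimization instances with controlled structure.

Real inputs for this problem come from curated pharmacology databases and
are not redistributable, so every other module is exercised on generated
instances instead.  The generator emulates the structural features that
matter to the optimizer: how many candidate drugs exist for a given drug,
how many disease-relevant main targets there are, how candidate coverage of
those targets is distributed, per-drug side-effect counts, and the density
of adverse drug-drug pairs.

Shape presets named after the nine study drugs (TRA, ATE, CAR, NIC, FEL,
NIF, NIS, DOX, PRA) reproduce the published instance shapes -- total
targets, main targets, candidate-pool size -- for example Nicardipine: 15
targets of which 4 are disease-relevant, with a pool of 40 candidate drugs.
Per-candidate side-effect counts are synthetic (drawn from a Poisson law)
because per-drug values were never published.

``plant_optimum`` builds instances whose global optimum is known by
construction (a designated subset partitions the main targets at zero side
effects while every other drug carries at least one), verified by the
exhaustive oracle before being returned; these anchor recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .baselines import OracleResult, exhaustive_oracle
from .interaction_store import (
    AdverseReactionMatrix,
    Candidate,
    CandidateDataset,
    DrugDiseaseMatrix,
    DrugTargetMatrix,
    EffectLabel,
    HTTargetSet,
)

__all__ = [
    "GeneratorSpec",
    "PRESETS",
    "preset_spec",
    "generate",
    "plant_optimum",
    "dataset_to_json",
    "dataset_from_json",
    "dataset_to_matrices",
]

_EFFECT_CYCLE = (EffectLabel.INH, EffectLabel.ANT, EffectLabel.AGO, EffectLabel.IND)

#: (total targets, main targets, candidate-pool size) per study-drug preset.
PRESETS: dict[str, tuple[int, int, int]] = {
    "TRA": (1, 1, 16),
    "ATE": (2, 1, 26),
    "CAR": (2, 2, 28),
    "NIC": (15, 4, 40),
    "FEL": (13, 5, 50),
    "NIF": (8, 5, 50),
    "NIS": (5, 5, 50),
    "DOX": (6, 3, 112),
    "PRA": (6, 3, 112),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic instance.

    ``se_rate`` is the Poisson mean of per-candidate side-effect counts
    (default 3: the study drugs' own residual-target counts range from 0 to
    11 with a typical value of a few).  ``coverage_p`` parameterizes the
    truncated geometric law of covered-subset sizes (default 0.5: most drugs
    hit a single main target, larger covered sets are exponentially rarer).
    ``ddar_density`` is the probability that an unordered candidate pair is
    adverse (default 0.05: adverse interactions are sparse).
    """

    n_candidates: int
    n_main_targets: int = 4
    se_rate: float = 3.0
    coverage_p: float = 0.5
    ddar_density: float = 0.05
    given_tnt: int | None = None  # total target count of the substituted drug
    name: str = "synthetic"
    seed: int = 0
    planted: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_candidates < 1:
            raise ValueError("need at least one candidate")
        if self.n_main_targets < 1:
            raise ValueError("need at least one main target")
        if not 0.0 <= self.ddar_density <= 1.0:
            raise ValueError("ddar_density must lie in [0, 1]")
        if not 0.0 < self.coverage_p <= 1.0:
            raise ValueError("coverage_p must lie in (0, 1]")
        if self.se_rate < 0:
            raise ValueError("se_rate must be nonnegative")


def preset_spec(name: str, seed: int = 0, **overrides) -> GeneratorSpec:
    """Spec with the (TNT, TNMT, TNC) shape of one study-drug preset."""
    tnt, tnmt, tnc = PRESETS[name.upper()]
    spec = GeneratorSpec(
        n_candidates=tnc,
        n_main_targets=tnmt,
        given_tnt=tnt,
        name=name.upper(),
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def _main_target_set(n: int) -> HTTargetSet:
    return HTTargetSet(
        [(f"T{i + 1:02d}", _EFFECT_CYCLE[i % len(_EFFECT_CYCLE)]) for i in range(n)]
    )


def _coverage_size(rng: np.random.Generator, n_targets: int, p: float) -> int:
    return min(n_targets, int(rng.geometric(p)))


def _adverse_pairs(
    rng: np.random.Generator,
    names: list[str],
    density: float,
    exclude: set[frozenset[str]] = frozenset(),
) -> set[tuple[str, str]]:
    pairs = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if frozenset((names[i], names[j])) in exclude:
                continue
            if rng.random() < density:
                pairs.add((names[i], names[j]))
    return pairs


def generate(spec: GeneratorSpec) -> CandidateDataset:
    """Draw one instance; deterministic for a given spec and seed."""
    rng = np.random.default_rng(spec.seed)
    main = _main_target_set(spec.n_main_targets)
    targets = main.targets()
    names = [f"D{i + 1:03d}" for i in range(spec.n_candidates)]
    candidates = []
    for name in names:
        size = _coverage_size(rng, spec.n_main_targets, spec.coverage_p)
        covered = frozenset(rng.choice(targets, size=size, replace=False).tolist())
        se = int(rng.poisson(spec.se_rate))
        candidates.append(Candidate(name, covered, se))
    exclude: set[frozenset[str]] = set()
    if spec.planted is not None:
        planted_names = [names[i] for i in spec.planted]
        exclude = {
            frozenset((a, b))
            for i, a in enumerate(planted_names)
            for b in planted_names[i + 1 :]
        }
    pairs = _adverse_pairs(rng, names, spec.ddar_density, exclude)
    return CandidateDataset(
        given_drug=f"GIVEN_{spec.name}",
        main_targets=main,
        candidates=candidates,
        adverse_pairs=pairs,
    )


def plant_optimum(
    spec: GeneratorSpec, k: int, max_retries: int = 100
) -> tuple[CandidateDataset, OracleResult]:
    """Instance whose unique global optimum is a designated k-subset.

    The k planted drugs partition the main targets into nonempty blocks and
    carry zero side effects; every other drug carries at least one.  The
    planted subset therefore attains full coverage at zero side-effect load,
    and any deviation either loses a target block or pays a positive average
    side-effect cost, so it is the strict optimum.  Verified against the
    exhaustive oracle (including uniqueness) before being returned.
    """
    if k < 1 or k > spec.n_candidates:
        raise ValueError("k must lie in [1, n_candidates]")
    if spec.n_candidates > 20:
        raise ValueError("planted instances are limited to 20 candidates (oracle bound)")
    if k > spec.n_main_targets:
        raise ValueError("cannot partition main targets into more blocks than targets")

    for attempt in range(max_retries):
        seed = spec.seed + 1_000_003 * attempt
        rng = np.random.default_rng(seed)
        main = _main_target_set(spec.n_main_targets)
        targets = main.targets()
        names = [f"D{i + 1:03d}" for i in range(spec.n_candidates)]
        planted_idx = sorted(
            rng.choice(spec.n_candidates, size=k, replace=False).tolist()
        )
        # partition targets into k nonempty blocks
        perm = rng.permutation(spec.n_main_targets)
        cuts = sorted(rng.choice(np.arange(1, spec.n_main_targets), size=k - 1, replace=False).tolist()) if k > 1 else []
        blocks = np.split(perm, cuts)
        candidates = []
        planted_set = set(planted_idx)
        block_iter = iter(blocks)
        for i, name in enumerate(names):
            if i in planted_set:
                block = next(block_iter)
                covered = frozenset(targets[j] for j in block)
                se = 0
            else:
                size = _coverage_size(rng, spec.n_main_targets, spec.coverage_p)
                covered = frozenset(rng.choice(targets, size=size, replace=False).tolist())
                se = 1 + int(rng.poisson(spec.se_rate))
            candidates.append(Candidate(name, covered, se))
        exclude = {
            frozenset((names[a], names[b]))
            for x, a in enumerate(planted_idx)
            for b in planted_idx[x + 1 :]
        }
        pairs = _adverse_pairs(rng, names, spec.ddar_density, exclude)
        dataset = CandidateDataset(
            given_drug=f"GIVEN_{spec.name}",
            main_targets=main,
            candidates=candidates,
            adverse_pairs=pairs,
        )
        oracle = exhaustive_oracle(dataset)
        expected = tuple(1 if i in planted_set else 0 for i in range(spec.n_candidates))
        if oracle.optimal_selection == expected and oracle.n_optima == 1:
            return dataset, oracle
    raise RuntimeError(f"planted-optimum construction failed after {max_retries} retries")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def dataset_to_json(dataset: CandidateDataset, path: str | Path | None = None) -> str:
    payload = {
        "given_drug": dataset.given_drug,
        "main_targets": [[t, e.value] for t, e in dataset.main_targets.entries],
        "candidates": [
            {"drug": c.drug, "covered": sorted(c.covered), "se": c.se}
            for c in dataset.candidates
        ],
        "adverse_pairs": sorted(map(list, dataset.adverse_pairs)),
    }
    text = json.dumps(payload, indent=1, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def dataset_from_json(source: str | Path) -> CandidateDataset:
    """Inverse of :func:`dataset_to_json`; accepts a path or raw JSON text."""
    if isinstance(source, Path):
        text = source.read_text()
    elif not source.lstrip().startswith("{") and len(source) < 4096:
        text = Path(source).read_text()
    else:
        text = source
    payload = json.loads(text)
    return CandidateDataset(
        given_drug=payload["given_drug"],
        main_targets=HTTargetSet(
            [(t, EffectLabel(e)) for t, e in payload["main_targets"]]
        ),
        candidates=[
            Candidate(c["drug"], frozenset(c["covered"]), c["se"])
            for c in payload["candidates"]
        ],
        adverse_pairs={tuple(p) for p in payload["adverse_pairs"]},
    )


def dataset_to_matrices(
    dataset: CandidateDataset, disease: str = "HT"
) -> tuple[DrugDiseaseMatrix, DrugTargetMatrix, AdverseReactionMatrix]:
    """Express an instance in the relational TSV dialect.

    The given drug is indicated for ``disease`` and hits every main target
    with the required effect; each candidate hits its covered targets with
    the required effect plus ``se`` private side targets.  Feeding the
    result through rule mining and instance construction reproduces the
    dataset, which is the round-trip the integration tests rely on.
    """
    required = dict(dataset.main_targets.entries)
    drugs = [dataset.given_drug] + dataset.drug_names
    cells: dict[tuple[str, str], EffectLabel] = {}
    targets: dict[str, None] = {}
    for t, eff in required.items():
        targets.setdefault(t, None)
        cells[(dataset.given_drug, t)] = eff
    classes = {t: "protein" for t in targets}
    for c in dataset.candidates:
        for t in sorted(c.covered):
            cells[(c.drug, t)] = required[t]
        for s in range(c.se):
            side = f"SIDE_{c.drug}_{s + 1}"
            targets.setdefault(side, None)
            classes[side] = "protein"
            cells[(c.drug, side)] = EffectLabel.INH
    dt = DrugTargetMatrix(drugs, list(targets), cells, classes)
    ddi = DrugDiseaseMatrix(drugs, [disease], {(dataset.given_drug, disease)})
    ddar = AdverseReactionMatrix(drugs, set(dataset.adverse_pairs))
    return ddi, dt, ddar
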