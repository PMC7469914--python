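"""Relational stores for drug-disease, drug-target and adverse-reaction data.

Three sparse binary/labelled matrices describe the raw pharmacology:

* drug-disease indications (which drug treats which disease),
* drug-target interactions labelled with a mechanism-of-action effect
  (inhibit, induce, agonize, antagonize),
* drug-drug adverse reactions (unordered pairs that must not co-occur in a
  combination).

Target-target relations (enzyme/protein edges carrying an effect label) feed
the rule miner.  :func:`build_candidate_dataset` turns the matrices plus a
mined drug set into one optimization instance: the candidate drugs, the main
targets each covers, its side-effect count, and the adverse pairs among the
candidates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "EffectLabel",
    "DrugDiseaseMatrix",
    "DrugTargetMatrix",
    "AdverseReactionMatrix",
    "TargetRelation",
    "HTTargetSet",
    "Candidate",
    "CandidateDataset",
    "EmptyInstanceError",
    "ValidationError",
    "load_matrices",
    "save_matrices",
    "build_candidate_dataset",
]


class ValidationError(ValueError):
    """Raised when an input file or in-memory structure violates an invariant."""


class EmptyInstanceError(ValueError):
    """Raised when a construction yields an instance with no candidates."""


class EffectLabel(enum.Enum):
    """Mechanism-of-action of a drug (or biomolecule) on a target.

    ``NONE`` encodes the absent-interaction cell of the drug-target matrix;
    it never appears in files or in required-effect sets.
    """

    INH = "INH"
    IND = "IND"
    AGO = "AGO"
    ANT = "ANT"
    NONE = "NONE"

    @classmethod
    def parse(cls, token: str, *, context: str = "") -> "EffectLabel":
        """Parse one of the four serialized tokens; anything else rejects."""
        try:
            label = cls[token]
        except KeyError:
            raise ValidationError(
                f"unknown effect label {token!r}{(' at ' + context) if context else ''}; "
                f"expected one of INH, IND, AGO, ANT"
            ) from None
        if label is cls.NONE:
            raise ValidationError(
                f"effect label NONE is not storable{(' at ' + context) if context else ''}"
            )
        return label


def _check_unique(ids: Sequence[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate {kind} identifiers")


@dataclass
class DrugDiseaseMatrix:
    """Binary drug-disease indication matrix, stored sparsely as a pair set."""

    drugs: list[str]
    diseases: list[str]
    pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        _check_unique(self.drugs, "drug")
        _check_unique(self.diseases, "disease")
        drugset, disset = set(self.drugs), set(self.diseases)
        for d, s in self.pairs:
            if d not in drugset or s not in disset:
                raise ValidationError(f"indication pair ({d}, {s}) outside identifier space")

    def indicated_drugs(self, disease: str) -> list[str]:
        if disease not in set(self.diseases):
            raise KeyError(f"unknown disease {disease!r}")
        return [d for d in self.drugs if (d, disease) in self.pairs]

    def cell(self, drug: str, disease: str) -> int:
        return 1 if (drug, disease) in self.pairs else 0


@dataclass
class DrugTargetMatrix:
    """Effect-labelled drug-target matrix; at most one label per (drug, target).

    ``target_classes`` records whether a target is an enzyme or a protein when
    the input provides it (the rule miner needs classes only on relations, so
    the map may be partial).
    """

    drugs: list[str]
    targets: list[str]
    cells: dict[tuple[str, str], EffectLabel] = field(default_factory=dict)
    target_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.drugs, "drug")
        _check_unique(self.targets, "target")
        drugset, tgtset = set(self.drugs), set(self.targets)
        for (d, t), eff in self.cells.items():
            if d not in drugset or t not in tgtset:
                raise ValidationError(f"interaction ({d}, {t}) outside identifier space")
            if eff is EffectLabel.NONE:
                raise ValidationError("NONE cells are encoded by absence, not stored")

    def effect(self, drug: str, target: str) -> EffectLabel:
        return self.cells.get((drug, target), EffectLabel.NONE)

    def targets_of(self, drug: str) -> dict[str, EffectLabel]:
        """All (target -> effect) interactions of one drug."""
        return {t: e for (d, t), e in self.cells.items() if d == drug}

    def drugs_hitting(self, target: str) -> dict[str, EffectLabel]:
        return {d: e for (d, t), e in self.cells.items() if t == target}


@dataclass
class AdverseReactionMatrix:
    """Symmetric zero-diagonal binary matrix over unordered drug pairs."""

    drugs: list[str]
    pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        _check_unique(self.drugs, "drug")
        drugset = set(self.drugs)
        canonical = set()
        for a, b in self.pairs:
            if a == b:
                raise ValidationError(f"adverse self-pair ({a}, {b})")
            if a not in drugset or b not in drugset:
                raise ValidationError(f"adverse pair ({a}, {b}) outside identifier space")
            canonical.add((a, b) if a < b else (b, a))
        self.pairs = canonical

    def adverse(self, a: str, b: str) -> bool:
        return ((a, b) if a < b else (b, a)) in self.pairs

    def restricted(self, drugs: Iterable[str]) -> "AdverseReactionMatrix":
        keep = set(drugs)
        return AdverseReactionMatrix(
            drugs=[d for d in self.drugs if d in keep],
            pairs={p for p in self.pairs if p[0] in keep and p[1] in keep},
        )


_TARGET_CLASSES = ("enzyme", "protein")


@dataclass(frozen=True)
class TargetRelation:
    """Directed enzyme/protein edge carrying the effect of source on sink."""

    source: str
    source_class: str
    sink: str
    sink_class: str
    effect: EffectLabel

    def __post_init__(self) -> None:
        if self.source == self.sink:
            raise ValidationError(f"self-relation on target {self.source!r}")
        for cls in (self.source_class, self.sink_class):
            if cls not in _TARGET_CLASSES:
                raise ValidationError(f"unknown target class {cls!r}")
        if self.effect is EffectLabel.NONE:
            raise ValidationError("relations must carry a real effect")


@dataclass
class HTTargetSet:
    """Disease-inducing targets with the effect required to counter them.

    Entries are (target, required effect) pairs; a conflicting pair for the
    same target (two indicated drugs acting differently on it) yields two
    entries, so targets alone need not be unique -- (target, effect) pairs are.
    """

    entries: list[tuple[str, EffectLabel]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("HT target set must contain at least one entry")
        if len(set(self.entries)) != len(self.entries):
            raise ValidationError("duplicate (target, effect) entries")
        if any(e is EffectLabel.NONE for _, e in self.entries):
            raise ValidationError("NONE is not a required effect")

    @property
    def n(self) -> int:
        return len(self.entries)

    def required(self, target: str) -> set[EffectLabel]:
        return {e for t, e in self.entries if t == target}

    def targets(self) -> list[str]:
        seen: list[str] = []
        for t, _ in self.entries:
            if t not in seen:
                seen.append(t)
        return seen


@dataclass(frozen=True)
class Candidate:
    """One candidate drug: the main targets it covers and its side-effect count."""

    drug: str
    covered: frozenset[str]
    se: int

    def __post_init__(self) -> None:
        if not self.covered:
            raise ValidationError(f"candidate {self.drug!r} covers no main target")
        if self.se < 0:
            raise ValidationError(f"candidate {self.drug!r} has negative side-effect count")


@dataclass
class CandidateDataset:
    """One optimization instance for combination selection.

    ``main_targets`` is the disease target set restricted to the drug being
    substituted; each candidate covers a nonempty subset of those targets with
    the required effect and carries ``se`` residual interactions (its total
    target count minus its covered-main-target count).  ``adverse_pairs`` is
    restricted to the candidates.
    """

    given_drug: str
    main_targets: HTTargetSet
    candidates: list[Candidate]
    adverse_pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.candidates:
            raise EmptyInstanceError(f"no candidates for {self.given_drug!r}")
        main = set(self.main_targets.targets())
        names = [c.drug for c in self.candidates]
        _check_unique(names, "candidate")
        nameset = set(names)
        for c in self.candidates:
            if not c.covered <= main:
                raise ValidationError(
                    f"candidate {c.drug!r} covers targets outside the main set"
                )
        canonical = set()
        for a, b in self.adverse_pairs:
            if a == b or a not in nameset or b not in nameset:
                raise ValidationError(f"bad adverse pair ({a}, {b})")
            canonical.add((a, b) if a < b else (b, a))
        self.adverse_pairs = canonical

    @property
    def m(self) -> int:
        """Number of candidates (length of a selection vector)."""
        return len(self.candidates)

    @property
    def drug_names(self) -> list[str]:
        return [c.drug for c in self.candidates]


# ---------------------------------------------------------------------------
# TSV serialization.  One relation per row, tab-separated, header required.
# ---------------------------------------------------------------------------

_FILES = {
    "drug_target": ("drug", "target", "target_class", "effect"),
    "drug_disease": ("drug", "disease"),
    "ddar": ("drug_a", "drug_b"),
    "target_relations": ("source", "source_class", "sink", "sink_class", "effect"),
}


def _read_tsv(path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {missing}")
    return df


def load_matrices(
    directory: str | Path,
) -> tuple[DrugDiseaseMatrix, DrugTargetMatrix, AdverseReactionMatrix, list[TargetRelation]]:
    """Load the four relational TSV files from ``directory``.

    Expects ``drug_target.tsv``, ``drug_disease.tsv``, ``ddar.tsv`` and
    ``target_relations.tsv``.  Identifier spaces are unified: the drug list is
    the union over all files, ordered by first appearance.  Unknown effect
    tokens raise :class:`ValidationError` naming the offending row.
    """
    directory = Path(directory)
    dt_df = _read_tsv(directory / "drug_target.tsv", _FILES["drug_target"])
    ddi_df = _read_tsv(directory / "drug_disease.tsv", _FILES["drug_disease"])
    ddar_df = _read_tsv(directory / "ddar.tsv", _FILES["ddar"])
    rel_df = _read_tsv(directory / "target_relations.tsv", _FILES["target_relations"])

    drugs: dict[str, None] = {}
    for col, frame in (("drug", dt_df), ("drug", ddi_df), ("drug_a", ddar_df), ("drug_b", ddar_df)):
        for name in frame[col]:
            drugs.setdefault(name, None)
    drug_list = list(drugs)

    targets: dict[str, None] = {}
    cells: dict[tuple[str, str], EffectLabel] = {}
    classes: dict[str, str] = {}
    for idx, row in enumerate(dt_df.itertuples(index=False), start=2):
        eff = EffectLabel.parse(row.effect, context=f"drug_target.tsv line {idx}")
        targets.setdefault(row.target, None)
        key = (row.drug, row.target)
        if key in cells and cells[key] is not eff:
            raise ValidationError(
                f"drug_target.tsv line {idx}: conflicting effect for {key}"
            )
        cells[key] = eff
        if row.target_class:
            if row.target_class not in _TARGET_CLASSES:
                raise ValidationError(
                    f"drug_target.tsv line {idx}: unknown target class {row.target_class!r}"
                )
            classes[row.target] = row.target_class
    dt = DrugTargetMatrix(drug_list, list(targets), cells, classes)

    diseases: dict[str, None] = {}
    for name in ddi_df["disease"]:
        diseases.setdefault(name, None)
    ddi = DrugDiseaseMatrix(
        drug_list, list(diseases), set(zip(ddi_df["drug"], ddi_df["disease"]))
    )

    ddar = AdverseReactionMatrix(
        drug_list, set(zip(ddar_df["drug_a"], ddar_df["drug_b"]))
    )

    relations = [
        TargetRelation(
            source=row.source,
            source_class=row.source_class,
            sink=row.sink,
            sink_class=row.sink_class,
            effect=EffectLabel.parse(
                row.effect, context=f"target_relations.tsv line {idx}"
            ),
        )
        for idx, row in enumerate(rel_df.itertuples(index=False), start=2)
    ]
    return ddi, dt, ddar, relations


def save_matrices(
    directory: str | Path,
    ddi: DrugDiseaseMatrix,
    dt: DrugTargetMatrix,
    ddar: AdverseReactionMatrix,
    relations: Sequence[TargetRelation] = (),
) -> None:
    """Write the four TSV files; inverse of :func:`load_matrices`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            (d, t, dt.target_classes.get(t, ""), e.value)
            for (d, t), e in sorted(dt.cells.items())
        ],
        columns=list(_FILES["drug_target"]),
    ).to_csv(directory / "drug_target.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(ddi.pairs), columns=list(_FILES["drug_disease"])
    ).to_csv(directory / "drug_disease.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(ddar.pairs), columns=list(_FILES["ddar"])
    ).to_csv(directory / "ddar.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (r.source, r.source_class, r.sink, r.sink_class, r.effect.value)
            for r in relations
        ],
        columns=list(_FILES["target_relations"]),
    ).to_csv(directory / "target_relations.tsv", sep="\t", index=False)


def build_candidate_dataset(
    given_drug: str,
    ht_targets: HTTargetSet,
    dt: DrugTargetMatrix,
    ddar: AdverseReactionMatrix,
    mined: Iterable[str],
) -> CandidateDataset:
    """Assemble the optimization instance for substituting ``given_drug``.

    The main targets are the disease targets the given drug itself hits with
    the required effect.  A mined drug becomes a candidate iff it hits at
    least one main target with exactly the required effect; partial matches
    contribute only their matching targets.  The side-effect count of a
    candidate is its total interaction count in ``dt`` minus the number of
    main targets it covers.
    """
    if given_drug not in set(dt.drugs):
        raise KeyError(f"given drug {given_drug!r} not in drug-target matrix")
    mined = set(mined)
    unknown = mined - set(dt.drugs)
    if unknown:
        raise ValidationError(f"mined drugs absent from matrix: {sorted(unknown)}")

    given_hits = dt.targets_of(given_drug)
    main_entries = [
        (t, r) for t, r in ht_targets.entries if given_hits.get(t) is r
    ]
    if not main_entries:
        raise EmptyInstanceError(
            f"{given_drug!r} hits no disease target with the required effect"
        )
    main = HTTargetSet(main_entries)
    required = {t: r for t, r in main_entries}

    candidates = []
    for drug in sorted(mined - {given_drug}):
        hits = dt.targets_of(drug)
        covered = frozenset(
            t for t, r in required.items() if hits.get(t) is r
        )
        if covered:
            candidates.append(Candidate(drug, covered, se=len(hits) - len(covered)))
    if not candidates:
        raise EmptyInstanceError(f"no mined drug covers a main target of {given_drug!r}")

    names = {c.drug for c in candidates}
    pairs = {p for p in ddar.pairs if p[0] in names and p[1] in names}
    return CandidateDataset(given_drug, main, candidates, pairs)
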