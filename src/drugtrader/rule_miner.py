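"""If-Then association rules admitting drugs into the candidate pool.

The disease's inducing targets, together with the effect required to counter
each of them, form the target set.  Five deterministic implication rules then
admit a drug:

1. the drug hits a disease target directly with exactly the required effect;
2. it hits an enzyme whose relation to a disease protein carries the
   required effect;
3. it hits a protein whose relation to a disease enzyme does;
4. protein-to-protein relation, likewise;
5. enzyme-to-enzyme relation, likewise.

Effect matching is strict label equality: a drug agonizing a receptor is not
admitted when the required effect is antagonism, even though both act on the
same target (the agonist would aggravate, not counter, the disease).  Each
admission carries a :class:`RuleTrace` recording the rule and the path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .interaction_store import (
    DrugDiseaseMatrix,
    DrugTargetMatrix,
    EffectLabel,
    HTTargetSet,
    TargetRelation,
    ValidationError,
)

__all__ = ["RuleTrace", "derive_ht_targets", "apply_rules", "load_ht_targets", "write_traces"]

logger = logging.getLogger(__name__)

# rule ids 2-5 by (source_class, sink_class) of the relation
_RELATION_RULE = {
    ("enzyme", "protein"): 2,
    ("protein", "enzyme"): 3,
    ("protein", "protein"): 4,
    ("enzyme", "enzyme"): 5,
}


@dataclass(frozen=True)
class RuleTrace:
    """Why a drug was admitted: the rule and the (entity, effect) hop path.

    Rule 1 paths have one hop (the matched target and the drug's effect on
    it); rules 2-5 have two (the intermediate target with the drug's effect,
    then the matched disease target with the relation's effect).
    """

    drug: str
    rule_id: int
    path: tuple[tuple[str, EffectLabel], ...]
    matched_target: str

    def __post_init__(self) -> None:
        if self.rule_id not in range(1, 6):
            raise ValidationError(f"rule id {self.rule_id} outside 1-5")
        expected = 1 if self.rule_id == 1 else 2
        if len(self.path) != expected:
            raise ValidationError(
                f"rule {self.rule_id} trace must have {expected} hop(s)"
            )


def derive_ht_targets(
    ddi: DrugDiseaseMatrix, dt: DrugTargetMatrix, disease: str
) -> HTTargetSet:
    """Union the (target, effect) pairs touched by drugs indicated for ``disease``.

    Deterministic: entries sorted by target identifier then effect token.
    When two indicated drugs act on the same target with conflicting effects
    both pairs are retained and the conflict is logged.
    """
    indicated = ddi.indicated_drugs(disease)  # raises KeyError if unknown
    if not indicated:
        raise ValidationError(f"no drugs indicated for disease {disease!r}")
    pairs: set[tuple[str, EffectLabel]] = set()
    for drug in indicated:
        pairs.update(dt.targets_of(drug).items())
    if not pairs:
        raise ValidationError(f"indicated drugs for {disease!r} touch no targets")
    by_target: dict[str, set[EffectLabel]] = {}
    for t, e in pairs:
        by_target.setdefault(t, set()).add(e)
    for t, effs in by_target.items():
        if len(effs) > 1:
            logger.warning(
                "target %s carries conflicting required effects %s; retaining all",
                t,
                sorted(e.value for e in effs),
            )
    return HTTargetSet(sorted(pairs, key=lambda te: (te[0], te[1].value)))


def apply_rules(
    dt: DrugTargetMatrix,
    relations: list[TargetRelation],
    ht: HTTargetSet,
) -> tuple[set[str], list[RuleTrace]]:
    """Admit drugs by the five implication rules; return the set plus traces.

    Relation chaining is exactly one hop: a relation admits the drugs hitting
    its source when its effect equals the required effect of its sink.  Empty
    output is valid.
    """
    required: dict[str, set[EffectLabel]] = {}
    for t, e in ht.entries:
        required.setdefault(t, set()).add(e)

    traces: list[RuleTrace] = []

    # rule 1: direct hit with the required effect
    for target, effects in required.items():
        for drug, eff in sorted(dt.drugs_hitting(target).items()):
            if eff in effects:
                traces.append(
                    RuleTrace(drug, 1, ((target, eff),), matched_target=target)
                )

    # rules 2-5: one relation hop into a disease target
    for rel in relations:
        if rel.effect not in required.get(rel.sink, ()):
            continue
        rule_id = _RELATION_RULE[(rel.source_class, rel.sink_class)]
        for drug, eff in sorted(dt.drugs_hitting(rel.source).items()):
            traces.append(
                RuleTrace(
                    drug,
                    rule_id,
                    ((rel.source, eff), (rel.sink, rel.effect)),
                    matched_target=rel.sink,
                )
            )

    return {t.drug for t in traces}, traces


def load_ht_targets(path: str | Path) -> HTTargetSet:
    """Read a curated (target, effect) TSV, bypassing matrix derivation."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("target", "effect"):
        if col not in df.columns:
            raise ValidationError(f"{Path(path).name}: missing column {col!r}")
    entries = [
        (row.target, EffectLabel.parse(row.effect, context=f"line {idx}"))
        for idx, row in enumerate(df.itertuples(index=False), start=2)
    ]
    return HTTargetSet(entries)


def write_traces(path: str | Path, traces: list[RuleTrace]) -> None:
    """Serialize admission traces as TSV: drug, rule_id, matched_target, path."""
    pd.DataFrame(
        [
            (
                t.drug,
                t.rule_id,
                t.matched_target,
                ";".join(f"{ent}:{eff.value}" for ent, eff in t.path),
            )
            for t in traces
        ],
        columns=["drug", "rule_id", "matched_target", "path"],
    ).to_csv(path, sep="\t", index=False)
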