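"""Chemical-formula parsing and the weighted drug-drug similarity score.

Drugs are compared through their molecular formulas: each formula is a
vector of element counts (Hill notation, e.g. C24H34N2O5), and the pairwise
score is a weighted agreement over shared elements.  The per-element weight

    w_r = min(d_r, 1) * min(C_i,r, C_j,r) / (max(C_i,r, C_j,r) + eps)

combines a corpus frequency d_r (how common the element is among the drugs
under study, clamped to 1) with the count agreement of the pair, so an
element contributes most when both drugs carry it in similar numbers.  Two
score modes ship:

* ``literal``     -- sum(w_r C_i,r C_j,r) / sum(w_r sqrt(C_i,r C_j,r)), the
                     printed form; its value is not bounded by 1;
* ``normalized``  -- the cosine form
                     sum(w_r C_i,r C_j,r) / sqrt(sum(w_r C_i,r^2) sum(w_r C_j,r^2)),
                     bounded in [0, 1] and the default for reporting.

Elements absent from either drug receive weight zero, so only the shared
support contributes; disjoint formulas score 0 in both modes.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ComponentVector",
    "ComponentWeights",
    "FormulaError",
    "parse_formula",
    "similarity",
    "load_formulas",
]

logger = logging.getLogger(__name__)

# the 118 IUPAC element symbols
_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr "
    "Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)

_SUBSCRIPT_MAP = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")


class FormulaError(ValueError):
    """Raised on an unparseable chemical formula."""


@dataclass(frozen=True)
class ComponentVector:
    """Element counts of one molecular formula."""

    components: Mapping[str, int]

    def __post_init__(self) -> None:
        for sym, count in self.components.items():
            if sym not in _ELEMENTS:
                raise FormulaError(f"unknown element symbol {sym!r}")
            if count < 1:
                raise FormulaError(f"component {sym!r} has nonpositive count {count}")

    @property
    def n(self) -> int:
        return len(self.components)

    def __getitem__(self, sym: str) -> int:
        return self.components.get(sym, 0)


@dataclass(frozen=True)
class ComponentWeights:
    """Corpus frequencies d_r in [0, 1] and the denominator guard eps.

    Without a corpus every element defaults to frequency 1 (no damping);
    values above 1 are clamped, so passing raw counts behaves like 1.
    """

    frequencies: Mapping[str, float] = field(default_factory=dict)
    default_frequency: float = 1.0
    eps: float = 1e-12

    @classmethod
    def from_corpus(cls, formulas: Iterable[ComponentVector], eps: float = 1e-12) -> "ComponentWeights":
        """d_r = fraction of corpus drugs whose formula contains element r."""
        formulas = list(formulas)
        if not formulas:
            raise ValueError("empty corpus")
        counts: dict[str, int] = {}
        for cv in formulas:
            for sym in cv.components:
                counts[sym] = counts.get(sym, 0) + 1
        n = len(formulas)
        return cls({sym: c / n for sym, c in counts.items()}, default_frequency=0.0, eps=eps)

    def frequency(self, sym: str) -> float:
        return min(self.frequencies.get(sym, self.default_frequency), 1.0)


_DIGITS = re.compile(r"\d+")


def parse_formula(text: str) -> ComponentVector:
    """Parse a Hill-notation formula into element counts.

    Implicit counts are 1; underscore subscript markers (C_24_H_34_...) and
    unicode subscript digits are tolerated.  Unknown element tokens raise
    :class:`FormulaError` naming the position.  A formula with many carbons
    but a single hydrogen is accepted verbatim with a plausibility warning
    (truncated-source formulas look like this).
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    cleaned = text.strip().translate(_SUBSCRIPT_MAP).replace("_", "")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        ch = cleaned[pos]
        if not ch.isupper():
            raise FormulaError(
                f"unexpected character {ch!r} at position {pos} in {text!r}"
            )
        # greedy two-letter symbol, back off to one letter if unknown
        two = cleaned[pos : pos + 2]
        if len(two) == 2 and two[1].islower() and two in _ELEMENTS:
            sym = two
        elif ch in _ELEMENTS and not (len(two) == 2 and two[1].islower()):
            sym = ch
        else:
            raise FormulaError(
                f"unknown element token {two!r} at position {pos} in {text!r}"
            )
        pos += len(sym)
        dmatch = _DIGITS.match(cleaned, pos)
        count = 1
        if dmatch:
            count = int(dmatch.group())
            pos = dmatch.end()
            if count < 1:
                raise FormulaError(f"zero count for {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + count
    if counts.get("C", 0) >= 5 and counts.get("H", 0) == 1:
        logger.warning(
            "formula %r parses with a single hydrogen against %d carbons; "
            "possibly truncated source text",
            text,
            counts["C"],
        )
    return ComponentVector(counts)


def _pair_weight(ca: int, cb: int, sym: str, weights: ComponentWeights) -> float:
    return weights.frequency(sym) * min(ca, cb) / (max(ca, cb) + weights.eps)


def similarity(
    a: ComponentVector,
    b: ComponentVector,
    weights: ComponentWeights | None = None,
    mode: str = "normalized",
) -> float:
    """Weighted formula similarity of two drugs (see module docstring)."""
    if a.n == 0 or b.n == 0:
        raise ValueError("component vectors must be nonempty")
    if mode not in ("literal", "normalized"):
        raise ValueError(f"unknown mode {mode!r}")
    weights = weights or ComponentWeights()

    shared = set(a.components) & set(b.components)
    if not shared:
        return 0.0
    num = 0.0
    if mode == "literal":
        den = 0.0
        for sym in shared:
            ca, cb = a[sym], b[sym]
            w = _pair_weight(ca, cb, sym, weights)
            num += w * ca * cb
            den += w * math.sqrt(ca * cb)
        return num / den if den > 0 else 0.0
    den_a = 0.0
    den_b = 0.0
    for sym in shared:
        ca, cb = a[sym], b[sym]
        w = _pair_weight(ca, cb, sym, weights)
        num += w * ca * cb
        den_a += w * ca * ca
        den_b += w * cb * cb
    den = math.sqrt(den_a) * math.sqrt(den_b)
    return num / den if den > 0 else 0.0


def load_formulas(path: str | Path) -> dict[str, ComponentVector]:
    """Read a two-column TSV (drug, formula) into parsed component vectors."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("drug", "formula"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing column {col!r}")
    return {row.drug: parse_formula(row.formula) for row in df.itertuples(index=False)}
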