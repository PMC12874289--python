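"""Monoisotopic mass arithmetic for bile acid modification inference.

The delta-mass reasoning this module supports: an unknown conjugate observed
at a precursor shift of +73.03 Da from the unmodified dihydroxy bile acid is
consistent with amide condensation of a C6H7NO amine (aminophenol) followed
by in-source water loss, because

    mass(C6H7NO) − 2·mass(H2O) = 109.0528 − 36.0211 = 73.0316 Da,

while the intact modification ion appears at

    mass(C6H7NO) + mass(H) = 110.0606 Da.

Note the hydrogen convention: the modification-ion arithmetic uses the
*hydrogen-atom* mass (1.0078250 Da), not the bare proton (1.0072765 Da) —
only the former reproduces the 110.0606 value to four decimals. Both
constants are exposed so callers can choose explicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormulaError

__all__ = [
    "MONOISOTOPIC_MASS",
    "WATER",
    "HYDROGEN_ATOM",
    "PROTON",
    "Formula",
    "DeltaAnnotation",
    "monoisotopic_mass",
    "modification_ion_mz",
    "net_conjugation_shift",
    "hydroxyl_to_ketone_shift",
    "annotate_delta",
    "load_formula_table",
    "builtin_formula_table",
]

#: Monoisotopic masses of the elements handled here (Da).
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

HYDROGEN_ATOM = 1.0078250319
PROTON = 1.00727646688
WATER = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]  # 18.0105646

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula:
    """An elemental composition in Hill notation, e.g. ``C6H7NO``."""

    __slots__ = ("counts",)

    def __init__(self, counts: Mapping[str, int]):
        cleaned = {el: int(n) for el, n in counts.items() if n}
        for el, n in cleaned.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}")
        if not cleaned:
            raise FormulaError("formula has no atoms")
        self.counts = cleaned

    @classmethod
    def from_string(cls, text: str) -> "Formula":
        text = text.strip()
        if not text:
            raise FormulaError("empty formula")
        counts: dict[str, int] = {}
        pos = 0
        for match in _TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r}")
            el, digits = match.groups()
            counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Formula) and self.counts == other.counts

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        order = sorted(self.counts, key=lambda el: (el != "C", el != "H", el))
        return "".join(f"{el}{self.counts[el] if self.counts[el] != 1 else ''}" for el in order)

    def __repr__(self) -> str:
        return f"Formula({self!s})"


def _as_formula(formula: "Formula | str") -> Formula:
    return formula if isinstance(formula, Formula) else Formula.from_string(formula)


def monoisotopic_mass(formula: "Formula | str") -> float:
    """Monoisotopic mass (Da) of a formula: Σ count·element mass."""
    f = _as_formula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts.items())


def modification_ion_mz(formula: "Formula | str") -> float:
    """m/z of the protonated modification fragment, using the H-atom convention.

    ``monoisotopic_mass(formula) + 1.0078250`` — e.g. C6H7NO → 110.0606 Th.
    """
    return monoisotopic_mass(formula) + HYDROGEN_ATOM


def net_conjugation_shift(formula: "Formula | str", water_losses: int) -> float:
    """Precursor mass shift of an amide conjugate relative to the free acid.

    ``water_losses=1`` is the amide condensation alone; ``water_losses=2``
    adds one in-source dehydration (e.g. C6H7NO → +73.03 Da).
    """
    if water_losses < 1:
        raise ValueError("water_losses must be at least 1")
    return monoisotopic_mass(formula) - water_losses * WATER


def hydroxyl_to_ketone_shift() -> float:
    """Mass lost when a hydroxyl is oxidised to a ketone: 2·H = 2.0157 Da."""
    return 2 * MONOISOTOPIC_MASS["H"]


@dataclass(frozen=True)
class DeltaAnnotation:
    """One candidate explanation of an observed precursor mass delta."""

    observed_delta: float
    candidate_formula: Formula
    theoretical_delta: float
    error_ppm: float
    interpretation: str


#: (label, number of waters lost, hydrogen-atom gain) interpretation grid.
_INTERPRETATIONS = (
    ("direct", 0, False),
    ("direct+H", 0, True),
    ("amide_condensation", 1, False),
    ("amide_condensation+H", 1, True),
    ("amide_plus_water_loss", 2, False),
    ("amide_plus_water_loss+H", 2, True),
)


def annotate_delta(
    observed_delta: float,
    formulas: Iterable["Formula | str"],
    tol_ppm: float = 10.0,
) -> list[DeltaAnnotation]:
    """Explain an observed mass delta with candidate formulas.

    Each candidate is tried under six interpretations: the intact formula,
    amide condensation (−1 H2O), condensation plus in-source dehydration
    (−2 H2O), each with and without a hydrogen-atom gain. Matches within
    ``tol_ppm`` (relative to the observed delta) are returned sorted by
    absolute ppm error. An empty result is a valid outcome.
    """
    if not tol_ppm > 0:
        raise ValueError("tol_ppm must be positive")
    candidates = [_as_formula(f) for f in formulas]
    if not candidates:
        raise ValueError("formula list must be non-empty")
    hits: list[DeltaAnnotation] = []
    for formula in candidates:
        base = monoisotopic_mass(formula)
        for label, waters, gain_h in _INTERPRETATIONS:
            theo = base - waters * WATER + (HYDROGEN_ATOM if gain_h else 0.0)
            if observed_delta == 0:
                continue
            err_ppm = (theo - observed_delta) / abs(observed_delta) * 1e6
            if abs(err_ppm) <= tol_ppm:
                hits.append(DeltaAnnotation(observed_delta, formula, theo, err_ppm, label))
    hits.sort(key=lambda a: abs(a.error_ppm))
    return hits


def load_formula_table(path: str | Path) -> dict[str, Formula]:
    """Read a candidate-formula TSV (columns: name, formula) into a dict."""
    frame = pd.read_csv(path, sep="\t")
    missing = {"name", "formula"} - set(frame.columns)
    if missing:
        raise FormulaError(f"formula table lacks columns: {sorted(missing)}")
    return {str(r["name"]): Formula.from_string(str(r["formula"])) for _, r in frame.iterrows()}


def builtin_formula_table() -> dict[str, Formula]:
    """Shipped candidate list: aminophenol plus common amine conjugates."""
    ref = resources.files("biletree").joinpath("data/formulas.tsv")
    with resources.as_file(ref) as path:
        return load_formula_table(path)
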