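"""Diagnostic-ion predicates evaluated against a single normalized spectrum.

These predicates are the computational core of the filtering approach: instead
of whole-spectrum similarity, a spectrum is interrogated for the presence,
absence, or intensity ratio of specific marker ions inside narrow m/z windows.
A :class:`Query` is the conjunction of such predicates and corresponds to one
node of a filtering tree.

Conventions (deliberate and documented):

* window lookups return the *maximum* relative intensity among in-window
  peaks, never a sum — robust to shoulder peaks and deterministic;
* an intensity-ratio predicate with an empty denominator window is ``False``
  regardless of the comparator: a missing marker ion must never positively
  place a spectrum in a bin.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass
from typing import Union

from .spectra import RelativeSpectrum

__all__ = [
    "DEFAULT_TOL_MZ",
    "IonPresence",
    "IonAbsence",
    "IntensityRatio",
    "Predicate",
    "Query",
    "ion_intensity",
    "evaluate_predicate",
    "evaluate_query",
]

#: Default absolute half-window (Th) around a diagnostic ion. Marker ions are
#: quoted to three decimals on Orbitrap-class data, so 0.01 Th is a
#: conservative window; it is configurable per predicate.
DEFAULT_TOL_MZ = 0.01

_COMPARATORS = {"<": operator.lt, "<=": operator.le, ">": operator.gt, ">=": operator.ge}


@dataclass(frozen=True)
class IonPresence:
    """Require an ion near ``target_mz`` at or above ``min_rel_intensity`` %.

    The default floor of 0 means any detected peak counts — diagnostic ions
    are characteristically low-intensity, so per-node floors are set in the
    tree configuration rather than here.
    """

    target_mz: float
    tol_mz: float = DEFAULT_TOL_MZ
    min_rel_intensity: float = 0.0

    def __post_init__(self) -> None:
        if not self.tol_mz > 0:
            raise ValueError("tol_mz must be positive")
        if not 0.0 <= self.min_rel_intensity <= 100.0:
            raise ValueError("min_rel_intensity must be in [0, 100]")


@dataclass(frozen=True)
class IonAbsence:
    """Fail when any in-window peak reaches ``max_rel_intensity`` % or more."""

    target_mz: float
    tol_mz: float = DEFAULT_TOL_MZ
    max_rel_intensity: float = 0.0

    def __post_init__(self) -> None:
        if not self.tol_mz > 0:
            raise ValueError("tol_mz must be positive")


@dataclass(frozen=True)
class IntensityRatio:
    """Compare the intensity ratio of two marker ions against a threshold.

    The ratio is max-in-window(numerator) / max-in-window(denominator). When
    the denominator window is empty the predicate is False for every
    comparator (zero-denominator rule).
    """

    numerator_mz: float
    denominator_mz: float
    comparator: str
    threshold: float
    tol_mz: float = DEFAULT_TOL_MZ

    def __post_init__(self) -> None:
        if self.numerator_mz == self.denominator_mz:
            raise ValueError("numerator and denominator m/z must differ")
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"comparator must be one of {sorted(_COMPARATORS)}")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")
        if not self.tol_mz > 0:
            raise ValueError("tol_mz must be positive")


Predicate = Union[IonPresence, IonAbsence, IntensityRatio]


@dataclass(frozen=True)
class Query:
    """A named conjunction of predicates; one per filtering-tree node."""

    name: str
    predicates: tuple[Predicate, ...]

    def __post_init__(self) -> None:
        preds = tuple(self.predicates)
        if not preds:
            raise ValueError(f"query {self.name!r} has no predicates")
        object.__setattr__(self, "predicates", preds)


def ion_intensity(spectrum: RelativeSpectrum, target_mz: float, tol_mz: float = DEFAULT_TOL_MZ) -> float:
    """Maximum relative intensity among peaks with \\|mz − target\\| ≤ tol; 0 if none."""
    if not tol_mz > 0:
        raise ValueError("tol_mz must be positive")
    best = 0.0
    for p in spectrum.peaks:
        if abs(p.mz - target_mz) <= tol_mz and p.intensity > best:
            best = p.intensity
    return best


def evaluate_predicate(spectrum: RelativeSpectrum, predicate: Predicate) -> bool:
    """Evaluate one predicate against a normalized spectrum."""
    if isinstance(predicate, IonPresence):
        inten = ion_intensity(spectrum, predicate.target_mz, predicate.tol_mz)
        # a peak must actually be detected: an empty window never satisfies
        # presence, even with a zero intensity floor
        return inten > 0 and inten >= predicate.min_rel_intensity
    if isinstance(predicate, IonAbsence):
        return ion_intensity(spectrum, predicate.target_mz, predicate.tol_mz) < predicate.max_rel_intensity
    if isinstance(predicate, IntensityRatio):
        den = ion_intensity(spectrum, predicate.denominator_mz, predicate.tol_mz)
        if den <= 0:
            return False
        num = ion_intensity(spectrum, predicate.numerator_mz, predicate.tol_mz)
        return _COMPARATORS[predicate.comparator](num / den, predicate.threshold)
    raise TypeError(f"unknown predicate type: {type(predicate).__name__}")


def evaluate_query(spectrum: RelativeSpectrum, query: Query) -> bool:
    """Conjunction over all predicates (short-circuiting, order-independent)."""
    return all(evaluate_predicate(spectrum, p) for p in query.predicates)
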