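"""Enumeration of theoretically possible bile acid steroid cores.

Hydroxylation of the 24-carbon steroid core at the positions reported from
human samples (C1, C3, C4, C6, C7, C11, C12, C15, C16, C22, C23), combined
with the α/β orientation of every hydroxyl and the allo (5α) versus non-allo
(5β) A/B ring fusion, spans the candidate space the filtering trees must
discriminate. With up to three hydroxyls the count is

    Σ_{k=1..3} C(11, k) · 2^k · 2  =  44 + 440 + 2640  =  3124.

Side-chain positions C22/C23 are treated with two stereo options each,
identically to ring positions — the only uniform convention consistent with
that total. Conjugate (amidation) combinatorics are deliberately excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from math import comb
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

__all__ = ["DEFAULT_POSITIONS", "CoreSpec", "EnumParams", "count_cores", "count_by_level", "enumerate_cores", "write_cores"]

#: Hydroxylation positions on the steroid core reported from human samples.
DEFAULT_POSITIONS = (1, 3, 4, 6, 7, 11, 12, 15, 16, 22, 23)

_STEREO = ("alpha", "beta")
_C5 = ("allo", "non_allo")


@dataclass(frozen=True)
class CoreSpec:
    """One candidate core: hydroxyl positions, their stereochemistry, C5 config."""

    hydroxyl_positions: tuple[int, ...]
    stereo: Mapping[int, str]
    c5_config: str

    def __post_init__(self) -> None:
        if set(self.stereo) != set(self.hydroxyl_positions):
            raise ValueError("stereo must be defined for exactly the hydroxyl positions")

    def label(self) -> str:
        """Human-readable label, e.g. ``3a,12a-(OH)2;5b``."""
        marks = {"alpha": "a", "beta": "b"}
        oh = ",".join(f"{p}{marks[self.stereo[p]]}" for p in self.hydroxyl_positions)
        ring = "5a" if self.c5_config == "allo" else "5b"
        return f"{oh}-(OH){len(self.hydroxyl_positions)};{ring}"


@dataclass(frozen=True)
class EnumParams:
    """Combinatorial assumptions for the enumeration.

    ``stereo_options_per_site`` and ``c5_options`` allow collapsing stereo
    or ring-fusion degrees of freedom (1 = ignore) for what-if counts.
    """

    positions: tuple[int, ...] = DEFAULT_POSITIONS
    max_oh: int = 3
    stereo_options_per_site: int = 2
    c5_options: int = 2

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("positions must be distinct")
        if self.max_oh < 1:
            raise ValueError("max_oh must be at least 1")
        if self.max_oh > len(self.positions):
            raise ValueError("max_oh cannot exceed the number of positions")
        if self.stereo_options_per_site not in (1, 2) or self.c5_options not in (1, 2):
            raise ValueError("stereo_options_per_site and c5_options must be 1 or 2")


def count_by_level(params: EnumParams = EnumParams()) -> dict[int, int]:
    """Closed-form count per hydroxylation level k: C(n,k)·stereo^k·c5."""
    n = len(params.positions)
    return {
        k: comb(n, k) * params.stereo_options_per_site**k * params.c5_options
        for k in range(1, params.max_oh + 1)
    }


def count_cores(params: EnumParams = EnumParams()) -> int:
    """Total number of distinct candidate cores (defaults give 3124)."""
    return sum(count_by_level(params).values())


def enumerate_cores(params: EnumParams = EnumParams()) -> Iterator[CoreSpec]:
    """Yield every distinct core, lexicographically by (positions, stereo, C5)."""
    positions = tuple(sorted(params.positions))
    stereo_opts = _STEREO[: params.stereo_options_per_site]
    c5_opts = _C5[: params.c5_options]
    for k in range(1, params.max_oh + 1):
        for sites in combinations(positions, k):
            for stereo_vec in product(stereo_opts, repeat=k):
                for c5 in c5_opts:
                    yield CoreSpec(sites, dict(zip(sites, stereo_vec)), c5)


def write_cores(params: EnumParams, path: str | Path) -> int:
    """Write the enumeration as TSV (positions, stereo, c5, label); return count."""
    rows = [
        {
            "positions": ",".join(map(str, c.hydroxyl_positions)),
            "stereo": ",".join(c.stereo[p] for p in c.hydroxyl_positions),
            "c5": c.c5_config,
            "label": c.label(),
        }
        for c in enumerate_cores(params)
    ]
    pd.DataFrame(rows, columns=["positions", "stereo", "c5", "label"]).to_csv(path, sep="\t", index=False)
    return len(rows)
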