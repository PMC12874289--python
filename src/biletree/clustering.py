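"""Greedy consensus clustering of redundant MS/MS spectra.

Binned spectra of the same bile acid recur many times across runs and
datasets; a reference library wants one representative per compound. Spectra
are clustered with a precursor-window gate plus a greedy cosine similarity
(defaults: 0.02 Th precursor, 0.05 Th fragment tolerance, minimum cosine 0.7,
minimum 6 matched peaks), and the member with the highest total ion current
represents each cluster.

The clustering is a deterministic single-pass procedure seeded in descending
TIC order. The cosine uses raw intensities (no square-root weighting) with
greedy one-to-one peak matching by descending intensity product, ties broken
by the smaller m/z difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = ["ClusterParams", "ClusterResult", "cosine_score", "cluster_spectra", "write_clusters"]


@dataclass(frozen=True)
class ClusterParams:
    """Clustering tolerances; defaults follow the library-generation settings."""

    precursor_tol: float = 0.02
    fragment_tol: float = 0.05
    min_cosine: float = 0.7
    min_matched_peaks: int = 6

    def __post_init__(self) -> None:
        if self.precursor_tol <= 0 or self.fragment_tol <= 0 or self.min_matched_peaks <= 0:
            raise ValueError("tolerances and min_matched_peaks must be positive")
        if not 0 < self.min_cosine <= 1:
            raise ValueError("min_cosine must be in (0, 1]")


@dataclass(frozen=True)
class ClusterResult:
    """One cluster: members plus the max-TIC representative."""

    cluster_id: int
    member_scan_ids: tuple[str, ...]
    representative_scan_id: str
    representative_tic: float


def cosine_score(a: Spectrum, b: Spectrum, fragment_tol: float = 0.05) -> tuple[float, int]:
    """Greedy cosine similarity between two spectra.

    Candidate peak pairs within ``fragment_tol`` are accepted greedily in
    descending order of intensity product (one-to-one), and the score is the
    sum of matched intensity products over the product of the spectrum norms.
    Returns ``(score, matched_peak_count)``.
    """
    mz_a, int_a = a.mz, a.intensity
    mz_b, int_b = b.mz, b.intensity
    pairs = []
    for i in range(len(mz_a)):
        for j in range(len(mz_b)):
            dmz = abs(mz_a[i] - mz_b[j])
            if dmz <= fragment_tol:
                pairs.append((int_a[i] * int_b[j], dmz, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    total = 0.0
    matched = 0
    for prod, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += prod
        matched += 1
    if matched == 0:
        return 0.0, 0
    norm = float(np.linalg.norm(int_a) * np.linalg.norm(int_b))
    return total / norm, matched


def cluster_spectra(spectra: Sequence[Spectrum], params: ClusterParams = ClusterParams()) -> list[ClusterResult]:
    """Single-pass greedy clustering seeded in descending TIC order.

    Each spectrum joins the first existing cluster (creation order) whose
    representative lies within the precursor tolerance and reaches the cosine
    and matched-peak thresholds; otherwise it seeds a new cluster. The
    representative is recomputed as the max-TIC member.
    """
    if not spectra:
        raise ValueError("spectra list must be non-empty")
    ordered = sorted(spectra, key=lambda s: (-s.tic, s.scan_id))
    reps: list[Spectrum] = []
    members: list[list[Spectrum]] = []
    for spectrum in ordered:
        placed = False
        for k, rep in enumerate(reps):
            if abs(spectrum.precursor_mz - rep.precursor_mz) > params.precursor_tol:
                continue
            score, matched = cosine_score(spectrum, rep, params.fragment_tol)
            if score >= params.min_cosine and matched >= params.min_matched_peaks:
                members[k].append(spectrum)
                placed = True
                break
        if not placed:
            reps.append(spectrum)
            members.append([spectrum])
    results = []
    for k, group in enumerate(members):
        rep = max(group, key=lambda s: (s.tic, s.scan_id))
        results.append(
            ClusterResult(
                cluster_id=k,
                member_scan_ids=tuple(s.scan_id for s in group),
                representative_scan_id=rep.scan_id,
                representative_tic=rep.tic,
            )
        )
    return results


def write_clusters(clusters: Sequence[ClusterResult], path: str | Path) -> pd.DataFrame:
    """Write clustering results as TSV (cluster_id, scan_id, is_representative, tic)."""
    rows = []
    for c in clusters:
        for scan in c.member_scan_ids:
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "scan_id": scan,
                    "is_representative": scan == c.representative_scan_id,
                    "tic": c.representative_tic if scan == c.representative_scan_id else "",
                }
            )
    frame = pd.DataFrame(rows, columns=["cluster_id", "scan_id", "is_representative", "tic"])
    frame.to_csv(path, sep="\t", index=False)
    return frame
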