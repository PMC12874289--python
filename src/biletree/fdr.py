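"""Per-bin specificity and false discovery rate against labelled references.

Each terminal bin of a filtering tree defines a retrieval query: the
reference spectra whose classification reaches that bin are "retrieved".
Against ground-truth isomer labels this yields TP/FP/FN/TN counts and

    FDR        = FP / (TP + FP)        (undefined when nothing is retrieved)
    specificity = TN / (TN + FP)

A bin may legitimately cover several true labels (e.g. a "3,12α or 7,12α"
bin covers both regioisomers); the ``label_map`` argument declares that
coverage. Evaluation is conjugate-agnostic: references are judged by their
core label regardless of the attached amine. Ambiguous classifications count
as retrieved for every matched bin — a conservative convention that
penalises promiscuous queries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .spectra import RelativeSpectrum, normalize, read_mgf
from .tree import TreeSpec, classify_spectrum

__all__ = [
    "ReferenceRecord",
    "QueryEvaluation",
    "evaluate_bin",
    "evaluate_tree",
    "load_references",
    "identity_label_map",
    "evaluations_frame",
]


@dataclass(frozen=True)
class ReferenceRecord:
    """A reference spectrum with its ground-truth isomer bin label."""

    spectrum: RelativeSpectrum
    true_label: str
    hydroxylation_level: str = "di"
    conjugate: str | None = None

    def __post_init__(self) -> None:
        if not self.true_label:
            raise ValueError("true_label must be non-empty")


@dataclass(frozen=True)
class QueryEvaluation:
    """Retrieval metrics of one terminal bin on a reference set.

    ``fdr`` is NaN with ``fdr_defined=False`` when the bin retrieved nothing;
    it is never reported as zero in that case.
    """

    bin_label: str
    retrieved: int
    true_positive: int
    false_positive: int
    false_negative: int
    true_negative: int
    fdr: float
    fdr_defined: bool
    specificity: float


def _matched_bins(record: ReferenceRecord, tree: TreeSpec) -> tuple[str, ...]:
    return classify_spectrum(record.spectrum, tree).matched_bins


def evaluate_bin(
    references: Sequence[ReferenceRecord],
    tree: TreeSpec,
    bin_label: str,
    label_map: Mapping[str, set[str] | frozenset[str] | Sequence[str]],
) -> QueryEvaluation:
    """Compute retrieval metrics for one terminal bin."""
    if not references:
        raise ValueError("reference set must be non-empty")
    if bin_label not in tree.leaf_names():
        raise ValueError(f"bin {bin_label!r} is not a terminal bin of tree {tree.tree_name!r}")
    covered = set(label_map.get(bin_label, {bin_label}))

    tp = fp = fn = tn = 0
    for record in references:
        retrieved = bin_label in _matched_bins(record, tree)
        correct = record.true_label in covered
        if retrieved and correct:
            tp += 1
        elif retrieved:
            fp += 1
        elif correct:
            fn += 1
        else:
            tn += 1
    retrieved_n = tp + fp
    fdr_defined = retrieved_n > 0
    fdr = fp / retrieved_n if fdr_defined else math.nan
    specificity = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    return QueryEvaluation(
        bin_label=bin_label,
        retrieved=retrieved_n,
        true_positive=tp,
        false_positive=fp,
        false_negative=fn,
        true_negative=tn,
        fdr=fdr,
        fdr_defined=fdr_defined,
        specificity=specificity,
    )


def evaluate_tree(
    references: Sequence[ReferenceRecord],
    tree: TreeSpec,
    label_map: Mapping[str, set[str]] | None = None,
) -> list[QueryEvaluation]:
    """One :class:`QueryEvaluation` per terminal bin of the tree."""
    label_map = label_map or {}
    return [evaluate_bin(references, tree, leaf, label_map) for leaf in tree.leaf_names()]


def identity_label_map(tree: TreeSpec) -> dict[str, set[str]]:
    """Label map where each bin covers exactly its own name."""
    return {leaf: {leaf} for leaf in tree.leaf_names()}


def load_references(mgf_path: str | Path, labels_path: str | Path) -> list[ReferenceRecord]:
    """Pair an MGF of reference spectra with a labels TSV by scan_id.

    The labels table needs columns scan_id and true_label; optional columns
    hydroxylation_level and conjugate are carried through.
    """
    spectra = {s.scan_id: s for s in read_mgf(mgf_path)}
    labels = pd.read_csv(labels_path, sep="\t", dtype={"scan_id": str}, keep_default_na=False)
    records = []
    for _, row in labels.iterrows():
        scan = str(row["scan_id"])
        if scan not in spectra:
            raise ValueError(f"labels reference scan {scan!r} absent from {mgf_path}")
        records.append(
            ReferenceRecord(
                spectrum=normalize(spectra[scan]),
                true_label=str(row["true_label"]),
                hydroxylation_level=str(row.get("hydroxylation_level", "di")),
                conjugate=str(row["conjugate"]) or None if "conjugate" in row else None,
            )
        )
    return records


def evaluations_frame(evaluations: Iterable[QueryEvaluation]) -> pd.DataFrame:
    """Serialise evaluations as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "bin_label": e.bin_label,
                "retrieved": e.retrieved,
                "true_positive": e.true_positive,
                "false_positive": e.false_positive,
                "false_negative": e.false_negative,
                "true_negative": e.true_negative,
                "fdr": e.fdr if e.fdr_defined else "undefined",
                "specificity": e.specificity,
            }
            for e in evaluations
        ]
    )
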