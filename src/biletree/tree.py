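"""Hierarchical filtering trees and sequential-intersection classification.

A filtering tree progressively narrows an MS/MS spectrum from a broad
hydroxylation class (the root query, e.g. the dihydroxy class ions at
m/z 321.26 and 339.27) down to a terminal isomer bin. Classification uses
*intersection semantics*: a spectrum reaches a leaf only if it satisfies the
query of every node on the root-to-leaf path. This sequential binning is the
step that suppresses false hits, and it is therefore not optional — there is
no flag to bypass it.

Trees are defined in editable YAML configuration files; three ship with the
package (``dihydroxy`` faithful to the described branch structure,
``monohydroxy``/``trihydroxy`` as skeletal templates). Numeric thresholds in
the shipped configs are placeholders calibrated on the synthetic fixtures and
are meant to be replaced with user-calibrated values for real instruments.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

from .errors import TreeConfigError
from .queries import (
    IntensityRatio,
    IonAbsence,
    IonPresence,
    Predicate,
    Query,
    evaluate_query,
)
from .spectra import RelativeSpectrum

__all__ = [
    "TreeNode",
    "TreeSpec",
    "BinAssignment",
    "load_tree",
    "builtin_tree",
    "BUILTIN_TREES",
    "classify_spectrum",
    "classify_dataset",
    "node_scan_sets",
]

logger = logging.getLogger(__name__)

#: Names of the filtering-tree configurations shipped with the package.
BUILTIN_TREES = ("monohydroxy", "dihydroxy", "trihydroxy")


@dataclass(frozen=True)
class TreeNode:
    """A tree node: a named query plus children; no children ⇒ terminal bin."""

    name: str
    query: Query
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class TreeSpec:
    """A validated filtering tree (root query = hydroxylation-class query)."""

    tree_name: str
    root: TreeNode

    def __post_init__(self) -> None:
        names: list[str] = []
        seen_ids: set[int] = set()

        def walk(node: TreeNode) -> None:
            if id(node) in seen_ids:
                raise TreeConfigError(
                    f"tree {self.tree_name!r}: node {node.name!r} appears on a cycle or is shared"
                )
            seen_ids.add(id(node))
            names.append(node.name)
            for child in node.children:
                walk(child)

        walk(self.root)
        dupes = [n for n, c in Counter(names).items() if c > 1]
        if dupes:
            raise TreeConfigError(f"tree {self.tree_name!r}: duplicate node names {dupes}")

    def iter_nodes(self) -> Iterator[tuple[TreeNode, tuple[str, ...]]]:
        """Yield (node, root-to-node name path) in depth-first pre-order."""

        def walk(node: TreeNode, path: tuple[str, ...]) -> Iterator[tuple[TreeNode, tuple[str, ...]]]:
            path = path + (node.name,)
            yield node, path
            for child in node.children:
                yield from walk(child, path)

        yield from walk(self.root, ())

    def leaf_names(self) -> list[str]:
        return [node.name for node, _ in self.iter_nodes() if node.is_leaf]

    def parent_of(self) -> dict[str, str | None]:
        """Map node name → parent name (root maps to ``None``)."""
        parents: dict[str, str | None] = {}
        for _, path in self.iter_nodes():
            parents[path[-1]] = path[-2] if len(path) > 1 else None
        return parents


@dataclass(frozen=True)
class BinAssignment:
    """The outcome of classifying one spectrum with one tree.

    ``node_path`` is the root-to-leaf path for an unambiguous assignment, the
    deepest satisfied path for a dead-end, the common prefix of all matched
    leaf paths for an ambiguous spectrum, and empty when the root query fails.
    """

    scan_id: str
    precursor_mz: float
    tree_name: str
    node_path: tuple[str, ...]
    terminal_bin: str | None
    ambiguous: bool
    matched_bins: tuple[str, ...]
    matched_paths: tuple[tuple[str, ...], ...] = ()

    @property
    def root_matched(self) -> bool:
        return bool(self.node_path)


# ---------------------------------------------------------------------------
# Configuration loading
# ---------------------------------------------------------------------------

def _parse_predicate(raw: Mapping, node_name: str) -> Predicate:
    kind = raw.get("type")
    try:
        if kind in ("presence", "ion_presence"):
            kwargs = {"target_mz": float(raw["target_mz"])}
            if "tol_mz" in raw:
                kwargs["tol_mz"] = float(raw["tol_mz"])
            if "min_rel_intensity" in raw:
                kwargs["min_rel_intensity"] = float(raw["min_rel_intensity"])
            return IonPresence(**kwargs)
        if kind in ("absence", "ion_absence"):
            kwargs = {"target_mz": float(raw["target_mz"])}
            if "tol_mz" in raw:
                kwargs["tol_mz"] = float(raw["tol_mz"])
            if "max_rel_intensity" in raw:
                kwargs["max_rel_intensity"] = float(raw["max_rel_intensity"])
            return IonAbsence(**kwargs)
        if kind in ("ratio", "intensity_ratio"):
            kwargs = {
                "numerator_mz": float(raw["numerator_mz"]),
                "denominator_mz": float(raw["denominator_mz"]),
                "comparator": str(raw["comparator"]),
                "threshold": float(raw["threshold"]),
            }
            if "tol_mz" in raw:
                kwargs["tol_mz"] = float(raw["tol_mz"])
            return IntensityRatio(**kwargs)
    except (KeyError, ValueError, TypeError) as exc:
        raise TreeConfigError(f"node {node_name!r}: bad predicate {raw!r}: {exc}") from exc
    raise TreeConfigError(f"node {node_name!r}: unknown predicate type {kind!r}")


def _parse_node(raw: Mapping) -> TreeNode:
    name = raw.get("name")
    if not name:
        raise TreeConfigError("every node needs a non-empty 'name'")
    preds = raw.get("predicates") or []
    if not preds:
        raise TreeConfigError(f"node {name!r} declares no predicates")
    query = Query(name=str(name), predicates=tuple(_parse_predicate(p, str(name)) for p in preds))
    children = tuple(_parse_node(c) for c in raw.get("children") or [])
    return TreeNode(name=str(name), query=query, children=children)


def load_tree(source: str | Path | Mapping) -> TreeSpec:
    """Build a validated :class:`TreeSpec` from a YAML file path or a mapping."""
    if isinstance(source, Mapping):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise TreeConfigError(f"{source}: tree config must be a mapping")
    tree_name = raw.get("tree_name")
    root_raw = raw.get("root")
    if not tree_name or root_raw is None:
        raise TreeConfigError("tree config requires 'tree_name' and 'root'")
    return TreeSpec(tree_name=str(tree_name), root=_parse_node(root_raw))


def builtin_tree(name: str) -> TreeSpec:
    """Load one of the shipped tree configurations by name."""
    if name not in BUILTIN_TREES:
        raise TreeConfigError(f"unknown builtin tree {name!r}; choose from {BUILTIN_TREES}")
    ref = resources.files("biletree").joinpath(f"configs/{name}.yaml")
    return load_tree(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _common_prefix(paths: Sequence[tuple[str, ...]]) -> tuple[str, ...]:
    prefix = paths[0]
    for p in paths[1:]:
        n = 0
        for a, b in zip(prefix, p):
            if a != b:
                break
            n += 1
        prefix = prefix[:n]
    return prefix


def classify_spectrum(spectrum: RelativeSpectrum, tree: TreeSpec) -> BinAssignment:
    """Classify one normalized spectrum by sequential tree traversal.

    A leaf is matched iff the spectrum satisfies the query of *every* node on
    the root-to-leaf path. Exactly one matched leaf gives an unambiguous
    assignment; several give an ambiguity record listing all matched bins;
    none (with the root satisfied) gives a dead-end record carrying the
    deepest satisfied node path.
    """
    matched_leaves: list[tuple[str, tuple[str, ...]]] = []
    deepest: tuple[str, ...] = ()

    def walk(node: TreeNode, path: tuple[str, ...]) -> None:
        nonlocal deepest
        if not evaluate_query(spectrum, node.query):
            return
        path = path + (node.name,)
        if len(path) > len(deepest):
            deepest = path
        if node.is_leaf:
            matched_leaves.append((node.name, path))
        for child in node.children:
            walk(child, path)

    walk(tree.root, ())

    if not deepest:  # root failed
        return BinAssignment(
            spectrum.scan_id, spectrum.precursor_mz, tree.tree_name,
            node_path=(), terminal_bin=None, ambiguous=False, matched_bins=(),
        )
    if len(matched_leaves) == 1:
        leaf, path = matched_leaves[0]
        return BinAssignment(
            spectrum.scan_id, spectrum.precursor_mz, tree.tree_name,
            node_path=path, terminal_bin=leaf, ambiguous=False,
            matched_bins=(leaf,), matched_paths=(path,),
        )
    if matched_leaves:
        paths = tuple(p for _, p in matched_leaves)
        return BinAssignment(
            spectrum.scan_id, spectrum.precursor_mz, tree.tree_name,
            node_path=_common_prefix(paths), terminal_bin=None, ambiguous=True,
            matched_bins=tuple(l for l, _ in matched_leaves), matched_paths=paths,
        )
    # dead-end: class filter passed but no isomer bin reached
    return BinAssignment(
        spectrum.scan_id, spectrum.precursor_mz, tree.tree_name,
        node_path=deepest, terminal_bin=None, ambiguous=False, matched_bins=(),
    )


def classify_dataset(
    spectra: Iterable[RelativeSpectrum], trees: Sequence[TreeSpec]
) -> list[BinAssignment]:
    """Classify every spectrum against every tree; keep records whose root matched."""
    if not trees:
        raise ValueError("at least one tree is required")
    assignments: list[BinAssignment] = []
    bin_counts: Counter[str] = Counter()
    for spectrum in spectra:
        for tree in trees:
            assignment = classify_spectrum(spectrum, tree)
            if assignment.root_matched:
                assignments.append(assignment)
                for b in assignment.matched_bins:
                    bin_counts[f"{tree.tree_name}:{b}"] += 1
    for key in sorted(bin_counts):
        logger.info("bin %s: %d scans", key, bin_counts[key])
    return assignments


def node_scan_sets(
    spectra: Iterable[RelativeSpectrum], tree: TreeSpec
) -> dict[str, set[str]]:
    """Scan-id set reaching each node under intersection semantics.

    By construction the set at any node is a subset of the set at its parent;
    this function exists so that property can be observed and audited.
    """
    sets: dict[str, set[str]] = {name: set() for _, path in tree.iter_nodes() for name in path}

    for spectrum in spectra:

        def walk(node: TreeNode) -> None:
            if not evaluate_query(spectrum, node.query):
                return
            sets[node.name].add(spectrum.scan_id)
            for child in node.children:
                walk(child)

        walk(tree.root)
    return sets
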