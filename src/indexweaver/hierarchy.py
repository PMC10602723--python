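"""Three-level evaluation-indicator hierarchies and weight aggregation.

An evaluation index system is a tree of indicators: first-level dimensions,
second-level sub-dimensions, and third-level (leaf) indicators.  Each node
carries a *local* weight — its share of importance among its siblings, as
elicited by AHP — and a *combination* weight, the product of local weights
along the path from its first-level ancestor down to the node.  Leaf
combination weights therefore partition the unit total across the whole
system.

Local weights in published tables are rounded (typically to 4 decimals), so
validation and the leaf-sum invariant use tolerances calibrated to that
rounding rather than exact arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from ._util import round_half_away

#: sibling local weights are expected to sum to 1 within this tolerance
#: (each printed weight carries up to 5e-5 rounding error; a sibling group
#: of ~10 accumulates at most ~5e-4)
SIBLING_SUM_TOL = 5e-4

#: leaf combination weights sum to 1 within this tolerance when every
#: sibling group satisfies SIBLING_SUM_TOL
LEAF_SUM_TOL = 2e-3


class HierarchyError(ValueError):
    """A structural problem that prevents computing on the hierarchy."""


@dataclass
class IndicatorNode:
    """One indicator in the tree.

    Parameters
    ----------
    id : str
        Unique key, e.g. ``"B3"``.
    label : str
        Display text, e.g. ``"Technical quality"``.
    level : int
        1 (dimension), 2 (sub-dimension) or 3 (leaf indicator).
    parent_id : str or None
        Key of the parent node; ``None`` iff ``level == 1``.
    local_weight : float or None
        Share of importance among siblings, in (0, 1].
    combination_weight : float or None
        Product of local weights on the root path; filled by
        :func:`combination_weights`.
    """

    id: str
    label: str
    level: int
    parent_id: str | None = None
    local_weight: float | None = None
    combination_weight: float | None = None


@dataclass
class Violation:
    """A single validation failure: which node, which rule, and details."""

    node_id: str
    rule: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.node_id}: {self.rule} ({self.detail})"


class IndexHierarchy:
    """An ordered collection of :class:`IndicatorNode` forming a forest.

    Nodes keep insertion (document) order, which defines the depth-first
    order used for tables and exports.
    """

    def __init__(self, nodes: Iterable[IndicatorNode] = ()):
        self._nodes: dict[str, IndicatorNode] = {}
        self._duplicates: list[str] = []
        for node in nodes:
            self.add(node)

    def add(self, node: IndicatorNode) -> None:
        if node.id in self._nodes:
            # remembered so validate_hierarchy can report instead of raise
            self._duplicates.append(node.id)
            return
        self._nodes[node.id] = node

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[IndicatorNode]:
        return iter(self._nodes.values())

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __getitem__(self, node_id: str) -> IndicatorNode:
        return self._nodes[node_id]

    @property
    def roots(self) -> list[IndicatorNode]:
        return [n for n in self._nodes.values() if n.parent_id is None]

    def children(self, node_id: str | None) -> list[IndicatorNode]:
        """Children of ``node_id`` in document order (``None`` → roots)."""
        return [n for n in self._nodes.values() if n.parent_id == node_id]

    def leaves(self) -> list[IndicatorNode]:
        parent_ids = {n.parent_id for n in self._nodes.values()}
        return [n for n in self._nodes.values() if n.id not in parent_ids]

    def depth_first(self) -> Iterator[IndicatorNode]:
        """Depth-first traversal following document order at every level."""

        def walk(parent: str | None) -> Iterator[IndicatorNode]:
            for child in self.children(parent):
                yield child
                yield from walk(child.id)

        return walk(None)

    # ---- serialisation -------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict) -> "IndexHierarchy":
        nodes = []
        for raw in doc["nodes"]:
            nodes.append(
                IndicatorNode(
                    id=str(raw["id"]),
                    label=str(raw.get("label", raw["id"])),
                    level=int(raw["level"]),
                    parent_id=raw.get("parent"),
                    local_weight=(
                        None if raw.get("local_weight") is None
                        else float(raw["local_weight"])
                    ),
                    combination_weight=(
                        None if raw.get("combination_weight") is None
                        else float(raw["combination_weight"])
                    ),
                )
            )
        return cls(nodes)

    def to_dict(self) -> dict:
        nodes = []
        for n in self._nodes.values():
            raw: dict = {
                "id": n.id,
                "label": n.label,
                "level": n.level,
                "parent": n.parent_id,
                "local_weight": n.local_weight,
            }
            if n.combination_weight is not None:
                raw["combination_weight"] = n.combination_weight
            nodes.append(raw)
        return {"nodes": nodes}

    @classmethod
    def from_json(cls, path: str | Path) -> "IndexHierarchy":
        with open(path, encoding="utf-8") as f:
            return cls.from_dict(json.load(f))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as f:
            json.dump(self.to_dict(), f, indent=1, ensure_ascii=False)
            f.write("\n")


def validate_hierarchy(hierarchy: IndexHierarchy) -> list[Violation]:
    """Check structural invariants; return a report of violations.

    Rules checked per node: unique id, known parent, parent level one less
    than the node's, roots exactly the level-1 nodes, local weight in
    (0, 1].  Per sibling group: local weights sum to 1 within
    :data:`SIBLING_SUM_TOL`.  An empty report means the hierarchy is valid.
    """
    report: list[Violation] = []
    for dup in hierarchy._duplicates:
        report.append(Violation(dup, "duplicate-id", "id used more than once"))

    for node in hierarchy:
        if node.parent_id is None:
            if node.level != 1:
                report.append(
                    Violation(node.id, "root-level",
                              f"level {node.level} node has no parent")
                )
        elif node.parent_id not in hierarchy:
            report.append(
                Violation(node.id, "orphan-parent",
                          f"parent {node.parent_id!r} not in hierarchy")
            )
        else:
            parent = hierarchy[node.parent_id]
            if node.level != parent.level + 1:
                report.append(
                    Violation(
                        node.id, "level-step",
                        f"level {node.level} under level {parent.level}",
                    )
                )
        if node.local_weight is not None and not (0 < node.local_weight <= 1):
            report.append(
                Violation(node.id, "weight-range",
                          f"local weight {node.local_weight} outside (0,1]")
            )

    # sibling-group sums (only for groups whose weights are all set)
    groups: dict[str | None, list[IndicatorNode]] = {}
    for node in hierarchy:
        if node.parent_id is None or node.parent_id in hierarchy:
            groups.setdefault(node.parent_id, []).append(node)
    for parent_id, members in groups.items():
        weights = [n.local_weight for n in members]
        if any(w is None for w in weights):
            continue
        total = sum(weights)  # type: ignore[arg-type]
        if abs(total - 1.0) > SIBLING_SUM_TOL:
            who = parent_id if parent_id is not None else "<roots>"
            report.append(
                Violation(who, "sibling-sum",
                          f"sibling sum {total:.4f} ≠ 1")
            )
    return report


def combination_weights(hierarchy: IndexHierarchy) -> IndexHierarchy:
    """Fill ``combination_weight`` on every node (in place; also returned).

    The combination weight of a root is its local weight; every other node
    multiplies its local weight by its parent's combination weight, so a
    node's combination weight is the product of local weights along its
    root path.
    """
    for node in hierarchy:
        if node.local_weight is None:
            raise HierarchyError(f"node {node.id!r} has no local weight")
    for node in hierarchy.depth_first():
        if node.parent_id is None:
            node.combination_weight = node.local_weight
        else:
            parent = hierarchy[node.parent_id]
            if parent.combination_weight is None:  # pragma: no cover
                raise HierarchyError(
                    f"parent {parent.id!r} visited out of order"
                )
            node.combination_weight = node.local_weight * parent.combination_weight
    return hierarchy


def leaf_weight_table(hierarchy: IndexHierarchy) -> pd.DataFrame:
    """Tabulate every node in depth-first document order.

    Columns: ``id, label, level, local_weight, combination_weight``.
    Requires :func:`combination_weights` to have been run (unless empty).
    """
    rows = []
    for node in hierarchy.depth_first():
        if node.combination_weight is None:
            raise HierarchyError(
                f"node {node.id!r} has no combination weight; "
                "run combination_weights first"
            )
        rows.append(
            {
                "id": node.id,
                "label": node.label,
                "level": node.level,
                "local_weight": node.local_weight,
                "combination_weight": node.combination_weight,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "label", "level", "local_weight", "combination_weight"],
    )


def rounded_weight_column(table: pd.DataFrame, ndigits: int = 4) -> pd.Series:
    """Combination weights re-rounded for display, ties away from zero."""
    return table["combination_weight"].map(lambda x: round_half_away(x, ndigits))
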