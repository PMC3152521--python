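"""Decision-tree representation and pathway roll-up.

A treatment pathway model is a rooted tree of chance and end nodes. Every
node carries the probability of the branch entering it from its parent and
an optional reference to a costed event. A root-to-leaf *pathway* then has

* probability = product of the branch probabilities along the path, and
* cost = sum of the event costs along the path,

and the expected (per-patient average) cost of the whole tree is the
probability-weighted sum of pathway costs. Pathway probabilities over a
valid tree always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping

import yaml

__all__ = [
    "NodeKind",
    "TreeNode",
    "Pathway",
    "TreeModel",
    "StructuralError",
    "MissingEventCostError",
    "ConservationError",
    "validate_tree",
    "enumerate_pathways",
    "expected_tree_cost",
    "recursive_expected_cost",
    "tree_to_dict",
    "tree_from_dict",
    "save_tree",
    "load_tree",
]

#: default tolerance for probability conservation on trees built in code
DEFAULT_TOLERANCE = 1e-9
#: looser tolerance for hand-entered configurations (rounded probabilities)
CONFIG_TOLERANCE = 1e-6


class StructuralError(ValueError):
    """The tree is malformed (duplicate id, wrong arity for its kind)."""


class MissingEventCostError(KeyError):
    """A node references an event id with no cost entry."""

    def __init__(self, event_id: str):
        super().__init__(event_id)
        self.event_id = event_id

    def __str__(self) -> str:  # KeyError repr-quotes its arg; be explicit
        return f"no cost available for event {self.event_id!r}"


class ConservationError(ValueError):
    """Pathway probabilities do not sum to one within tolerance."""


class NodeKind(str, Enum):
    CHANCE = "chance"
    END = "end"


@dataclass
class TreeNode:
    """One node of the decision tree.

    Parameters
    ----------
    id:
        Unique label; the packaged insomnia model uses hierarchical dotted
        labels such as ``"2.2.2.1"``.
    kind:
        ``chance`` (has branches) or ``end`` (terminates a pathway).
    branch_probability:
        Probability of taking the branch that enters this node from its
        parent; 1.0 at the root.
    event_id:
        Key into an event-cost mapping, or ``None`` for purely structural
        nodes that consume no resources.
    """

    id: str
    kind: NodeKind
    branch_probability: float = 1.0
    event_id: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def walk(self) -> Iterator["TreeNode"]:
        """Depth-first pre-order traversal."""
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Pathway:
    """A root-to-leaf path with its probability and dollar cost."""

    nodes: tuple[str, ...]
    probability: float
    cost: float

    @property
    def leaf(self) -> str:
        return self.nodes[-1]


@dataclass
class TreeModel:
    root: TreeNode
    name: str = ""
    currency_year: int = 2009

    def nodes(self) -> Iterator[TreeNode]:
        return self.root.walk()

    def find(self, node_id: str) -> TreeNode:
        for node in self.nodes():
            if node.id == node_id:
                return node
        raise KeyError(node_id)


def validate_tree(
    tree: TreeModel,
    tolerance: float = DEFAULT_TOLERANCE,
    event_ids: set[str] | None = None,
) -> list[str]:
    """Check probability semantics; return a list of human-readable findings.

    Structural defects (duplicate ids, an end node with children, a chance
    node without children) raise :class:`StructuralError` — they make the
    probability findings meaningless. Probability problems (branch
    probability outside [0, 1], a chance node whose child probabilities do
    not sum to 1 within ``tolerance``) and, when ``event_ids`` is given,
    unresolvable event references, are returned as findings. An empty list
    means the tree is valid.
    """
    seen: set[str] = set()
    for node in tree.nodes():
        if node.id in seen:
            raise StructuralError(f"duplicate node id {node.id!r}")
        seen.add(node.id)
        if node.kind == NodeKind.END and node.children:
            raise StructuralError(f"end node {node.id!r} has children")
        if node.kind == NodeKind.CHANCE and not node.children:
            raise StructuralError(f"chance node {node.id!r} has no children")

    findings: list[str] = []
    if abs(tree.root.branch_probability - 1.0) > tolerance:
        findings.append(
            f"root {tree.root.id!r} has branch probability "
            f"{tree.root.branch_probability!r}, expected 1"
        )
    for node in tree.nodes():
        if not 0.0 <= node.branch_probability <= 1.0:
            findings.append(
                f"node {node.id!r} branch probability "
                f"{node.branch_probability!r} outside [0, 1]"
            )
        if node.kind == NodeKind.CHANCE:
            total = sum(c.branch_probability for c in node.children)
            if abs(total - 1.0) > tolerance:
                findings.append(
                    f"children of chance node {node.id!r} "
                    f"have probabilities summing to {total:.6g}, expected 1"
                )
        if (
            event_ids is not None
            and node.event_id is not None
            and node.event_id not in event_ids
        ):
            findings.append(
                f"node {node.id!r} references unknown event {node.event_id!r}"
            )
    return findings


def enumerate_pathways(
    tree: TreeModel, event_costs: Mapping[str, float]
) -> list[Pathway]:
    """List every root-to-leaf pathway with its probability and cost.

    Nodes with ``event_id`` ``None`` contribute zero cost. Raises
    :class:`MissingEventCostError` if a node on any path references an
    event absent from ``event_costs``.
    """

    def node_cost(node: TreeNode) -> float:
        if node.event_id is None:
            return 0.0
        try:
            return float(event_costs[node.event_id])
        except KeyError:
            raise MissingEventCostError(node.event_id) from None

    pathways: list[Pathway] = []

    def descend(node: TreeNode, ids: tuple[str, ...], p: float, c: float) -> None:
        ids = ids + (node.id,)
        p = p * node.branch_probability
        c = c + node_cost(node)
        if not node.children:
            pathways.append(Pathway(nodes=ids, probability=p, cost=c))
        else:
            for child in node.children:
                descend(child, ids, p, c)

    descend(tree.root, (), 1.0, 0.0)
    return pathways


def expected_tree_cost(
    pathways: list[Pathway], tolerance: float = CONFIG_TOLERANCE
) -> float:
    """Probability-weighted mean pathway cost (the per-patient tree cost).

    Raises :class:`ConservationError` if the pathway probabilities do not
    sum to one within ``tolerance``.
    """
    total_p = sum(p.probability for p in pathways)
    if abs(total_p - 1.0) > tolerance:
        raise ConservationError(
            f"pathway probabilities sum to {total_p!r}, expected 1"
        )
    return sum(p.probability * p.cost for p in pathways)


def recursive_expected_cost(
    tree: TreeModel, event_costs: Mapping[str, float]
) -> float:
    """Expected cost by direct roll-back, node by node.

    Independent of pathway enumeration: E[subtree] = own event cost +
    Σ p_child · E[child subtree]. Used as a cross-check oracle.
    """

    def expect(node: TreeNode) -> float:
        own = float(event_costs[node.event_id]) if node.event_id else 0.0
        return own + sum(
            c.branch_probability * expect(c) for c in node.children
        )

    return expect(tree.root)


# ---------------------------------------------------------------------------
# Structured-text (YAML) serialisation


def tree_to_dict(tree: TreeModel) -> dict:
    def node_dict(node: TreeNode) -> dict:
        d: dict = {"id": node.id, "kind": node.kind.value, "p": node.branch_probability}
        if node.event_id is not None:
            d["event"] = node.event_id
        if node.children:
            d["children"] = [node_dict(c) for c in node.children]
        return d

    return {
        "name": tree.name,
        "currency_year": tree.currency_year,
        "root": node_dict(tree.root),
    }


def tree_from_dict(data: Mapping) -> TreeModel:
    def build(d: Mapping) -> TreeNode:
        return TreeNode(
            id=str(d["id"]),
            kind=NodeKind(d["kind"]),
            branch_probability=float(d.get("p", 1.0)),
            event_id=d.get("event"),
            children=[build(c) for c in d.get("children", [])],
        )

    return TreeModel(
        root=build(data["root"]),
        name=str(data.get("name", "")),
        currency_year=int(data.get("currency_year", 2009)),
    )


def save_tree(tree: TreeModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(tree_to_dict(tree), fh, sort_keys=False)


def load_tree(path) -> TreeModel:
    with open(path) as fh:
        return tree_from_dict(yaml.safe_load(fh))
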