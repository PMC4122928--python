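"""Gene trees: surviving gene lineages with speciation/duplication annotation.

Leaves are ``(species, copy_index)`` pairs written as ``SPECIES__copyN`` in
Newick.  Internal nodes are tagged ``"speciation"`` or ``"duplication"``
(either by the simulator, which knows the truth, or by LCA reconciliation).
Loss events are kept alongside the tree as ``{species-tree branch: count}``
because pruned (fully extinct) sub-lineages leave no trace in the topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import dendropy

__all__ = ["GeneNode", "GeneTree"]


class GeneNode:
    """Node of a gene tree; ``species`` is set on leaves only."""

    __slots__ = ("children", "species", "copy_index", "event", "mapping")

    def __init__(
        self,
        children: Optional[List["GeneNode"]] = None,
        species: Optional[str] = None,
        copy_index: int = 0,
        event: Optional[str] = None,
    ) -> None:
        self.children: List["GeneNode"] = children or []
        self.species = species
        self.copy_index = copy_index
        self.event = event  # "speciation" | "duplication" | None
        self.mapping: Optional[str] = None  # species-tree node set by reconciliation

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> List["GeneNode"]:
        out: List[GeneNode] = []
        stack: List[Tuple[GeneNode, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))
        return out

    def label(self) -> str:
        if self.is_leaf:
            return f"{self.species}__copy{self.copy_index}"
        return ""


@dataclass
class GeneTree:
    """Rooted gene tree of surviving copies plus unobservable loss counts."""

    root: GeneNode
    losses: Dict[str, int] = field(default_factory=dict)

    def leaves(self) -> List[GeneNode]:
        return [n for n in self.root.postorder() if n.is_leaf]

    def leaf_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for n in self.leaves():
            counts[n.species] = counts.get(n.species, 0) + 1
        return counts

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def duplication_nodes(self) -> List[GeneNode]:
        return [n for n in self.root.postorder() if n.event == "duplication"]

    # -- Newick I/O (labels SPECIES__copyN) --------------------------------

    def to_newick(self) -> str:
        def rec(node: GeneNode) -> str:
            if node.is_leaf:
                return node.label()
            return "(" + ",".join(rec(c) for c in node.children) + ")"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "GeneTree":
        dtree = dendropy.Tree.get(data=text, schema="newick")
        nodes: Dict[int, GeneNode] = {}
        root = None
        for nd in dtree.postorder_node_iter():
            if nd.is_leaf():
                lab = (nd.taxon.label if nd.taxon else nd.label) or ""
                lab = lab.replace(" ", "_")
                if "__copy" in lab:
                    sp, _, idx = lab.partition("__copy")
                    try:
                        ci = int(idx)
                    except ValueError as exc:
                        raise ValueError(f"bad gene-tree leaf label {lab!r}") from exc
                else:
                    sp, ci = lab, 1
                nodes[id(nd)] = GeneNode(species=sp, copy_index=ci)
            else:
                nodes[id(nd)] = GeneNode(children=[nodes[id(c)] for c in nd.child_nodes()])
            root = nodes[id(nd)]
        if root is None:
            raise ValueError("empty gene tree")
        # suppress unary internal nodes (e.g. from rooted-newick artifacts)
        root = _suppress_unary(root)
        return cls(root=root)


def _suppress_unary(node: GeneNode) -> GeneNode:
    node.children = [_suppress_unary(c) for c in node.children]
    if len(node.children) == 1:
        return node.children[0]
    return node
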