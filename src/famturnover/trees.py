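"""Dated species trees and branch rate-class labelling.

A :class:`DatedTree` is a rooted, strictly bifurcating, ultrametric species
tree whose branch lengths are durations in millions of years (Myr).  Branches
are identified by their child node: a tree with ``n`` leaves has ``2n - 2``
branches and the root carries none.  The 11-species *Drosophila* tree used
throughout the simulation experiments ships as a packaged data file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Tuple

import dendropy

__all__ = [
    "DatedTree",
    "BranchClassLabel",
    "parse_dated_newick",
    "fixture_drosophila_tree",
    "label_branches",
    "MODEL_NAMES",
    "model_param_count",
]

#: Relative tolerance for the ultrametricity check; divergence dates in
#: published chronograms are rounded, so exact equality is not expected.
ULTRAMETRIC_RTOL = 1e-6

#: Ecology-motivated terminal-branch groupings behind the named branch models.
_FOREGROUND_SETS = {
    "Msec": ("sechellia",),
    "Mgri": ("grimshawi",),
    "Mspe": ("sechellia", "erecta", "mojavensis"),
    "Mend": ("sechellia", "grimshawi"),
    "Mspeend": ("sechellia", "erecta", "mojavensis", "grimshawi"),
}

#: ``Mterm`` is not one of the ecological models: it is the two-class
#: internal/terminal model used as the nuisance-internal null in
#: heterogeneity LRTs (every ecological model nests it).
MODEL_NAMES = ("MGr", "Mterm", "Msec", "Mgri", "Mspe", "Mend", "Mspeend", "Mspe-end-sec", "MFr")


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a :class:`DatedTree` invariant."""


@dataclass
class DatedTree:
    """Rooted, bifurcating, ultrametric species tree with branch durations.

    Nodes are stored in postorder (root last).  ``parent[i]`` is the index of
    the parent of node ``i`` (``-1`` for the root) and ``duration[i]`` the
    length in Myr of the branch above node ``i`` (undefined for the root).
    """

    labels: List[str]
    parent: List[int]
    children: List[List[int]]
    duration: List[float]

    index: Dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self.index) != len(self.labels):
            raise TreeValidationError("node labels must be unique")
        self.validate()

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def root_index(self) -> int:
        return self.parent.index(-1)

    @property
    def root(self) -> str:
        return self.labels[self.root_index]

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaves(self) -> List[str]:
        return [lab for i, lab in enumerate(self.labels) if self.is_leaf(i)]

    @property
    def branch_ids(self) -> List[str]:
        """Branches named by their child node, in postorder (root excluded)."""
        r = self.root_index
        return [lab for i, lab in enumerate(self.labels) if i != r]

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def postorder(self) -> List[int]:
        return list(range(self.n_nodes))

    def preorder(self) -> List[int]:
        return list(range(self.n_nodes))[::-1]

    def branch_duration(self, branch_id: str) -> float:
        return self.duration[self.index[branch_id]]

    def depth(self, i: int) -> int:
        """Number of branches between node ``i`` and the root."""
        d = 0
        while self.parent[i] != -1:
            i = self.parent[i]
            d += 1
        return d

    def age(self, i: int) -> float:
        """Time before present (Myr) of node ``i``; leaves sit at 0."""
        # depth from root, subtracted from the root age
        path = 0.0
        j = i
        while self.parent[j] != -1:
            path += self.duration[j]
            j = self.parent[j]
        return self.root_age - path

    @property
    def root_age(self) -> float:
        i = self.root_index
        total = 0.0
        j = i
        while not self.is_leaf(j):
            j = self.children[j][0]
            total += self.duration[j]
        return total

    def mrca(self, a: str, b: str) -> str:
        anc = set()
        i = self.index[a]
        while i != -1:
            anc.add(i)
            i = self.parent[i]
        j = self.index[b]
        while j not in anc:
            j = self.parent[j]
        return self.labels[j]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        r = self.root_index
        for i in range(self.n_nodes):
            nc = len(self.children[i])
            if nc not in (0, 2):
                raise TreeValidationError(
                    f"node {self.labels[i]!r} has {nc} children; tree must be "
                    "strictly bifurcating"
                )
            if i != r and not self.duration[i] > 0:
                raise TreeValidationError(
                    f"branch above {self.labels[i]!r} has non-positive duration"
                )
        # postorder: every child index precedes its parent
        for i in range(self.n_nodes):
            for c in self.children[i]:
                if c >= i:
                    raise TreeValidationError("nodes are not in postorder")
        self._check_ultrametric()

    def _check_ultrametric(self) -> None:
        depths: Dict[int, float] = {}
        for i in self.preorder():
            p = self.parent[i]
            depths[i] = 0.0 if p == -1 else depths[p] + self.duration[i]
        leaf_depths = {self.labels[i]: depths[i] for i in range(self.n_nodes) if self.is_leaf(i)}
        ref_leaf = min(leaf_depths)
        ref = leaf_depths[ref_leaf]
        scale = max(abs(v) for v in leaf_depths.values()) or 1.0
        for leaf, d in leaf_depths.items():
            if abs(d - ref) > ULTRAMETRIC_RTOL * scale:
                raise TreeValidationError(
                    f"tree is not ultrametric: root-to-leaf durations differ "
                    f"between {ref_leaf!r} ({ref:g}) and {leaf!r} ({d:g})"
                )

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if self.is_leaf(i):
                body = self.labels[i]
            else:
                body = "(" + ",".join(rec(c) for c in self.children[i]) + ")" + self.labels[i]
            if self.parent[i] == -1:
                return body
            return f"{body}:{self.duration[i]:.10g}"

        return rec(self.root_index) + ";"

    def branch_table(self) -> List[Tuple[str, float]]:
        """(branch_id, duration) rows in postorder; the serialization contract."""
        return [(b, self.branch_duration(b)) for b in self.branch_ids]


def parse_dated_newick(text: str) -> DatedTree:
    """Parse a Newick string with branch lengths into a :class:`DatedTree`.

    Raises a parse error for malformed Newick and a
    :class:`TreeValidationError` for trees that are not strictly bifurcating,
    have non-positive branch durations, or are not ultrametric (the error
    names the offending leaf pair).
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=False)
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc

    labels: List[str] = []
    parent: List[int] = []
    children: List[List[int]] = []
    duration: List[float] = []
    idx: Dict[int, int] = {}

    auto = 0
    seen = set()
    for node in dtree.postorder_node_iter():
        if node.taxon is not None and node.taxon.label:
            lab = node.taxon.label.replace(" ", "_")
        elif node.label:
            lab = node.label.replace(" ", "_")
        else:
            auto += 1
            lab = f"N{auto}"
            while lab in seen:
                auto += 1
                lab = f"N{auto}"
        if lab in seen:
            raise TreeValidationError(f"duplicate node label {lab!r}")
        seen.add(lab)
        i = len(labels)
        idx[id(node)] = i
        labels.append(lab)
        parent.append(-1)
        children.append([idx[id(c)] for c in node.child_nodes()])
        duration.append(node.edge.length if node.edge.length is not None else float("nan"))
        for c in node.child_nodes():
            parent[idx[id(c)]] = i

    root = parent.index(-1)
    for i in range(len(labels)):
        if i != root and duration[i] != duration[i]:  # NaN
            raise TreeValidationError(f"branch above {labels[i]!r} has no length")
    duration[root] = 0.0
    return DatedTree(labels=labels, parent=parent, children=children, duration=duration)


def fixture_drosophila_tree() -> DatedTree:
    """The 11-species *Drosophila* tree with divergence dates in Myr.

    Topology ``((((((mel,(sim,sech)),(yak,ere)),ana),pse),wil),((moj,vir),gri))``
    with node ages transcribed from the standard *Drosophila* chronogram
    (root 62.9 Mya).  Loaded from the packaged ``data/drosophila11.nwk``.
    """
    text = resources.files("famturnover").joinpath("data/drosophila11.nwk").read_text()
    return parse_dated_newick(text)


@dataclass
class BranchClassLabel:
    """Assignment of every branch (keyed by child node) to one rate class."""

    classes: Dict[str, str]

    def class_names(self) -> List[str]:
        seen: List[str] = []
        for c in self.classes.values():
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def n_classes(self) -> int:
        return len(self.class_names())

    def branches_in(self, class_name: str) -> List[str]:
        return [b for b, c in self.classes.items() if c == class_name]

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("branch_id\tclass\n")
        for b, c in self.classes.items():
            buf.write(f"{b}\t{c}\n")
        return buf.getvalue()


def label_branches(
    tree: DatedTree,
    model_name: str,
    custom_map: Optional[Dict[str, str]] = None,
) -> BranchClassLabel:
    """Label every branch of ``tree`` with the rate class of a named model.

    ``MGr`` puts all branches in one class.  The six-parameter ecological
    models (``Msec``, ``Mgri``, ``Mspe``, ``Mend``, ``Mspeend``) distinguish
    internal branches, the focal terminal branch(es), and the remaining
    terminal branches.  ``Mspe-end-sec`` splits the focal terminals into
    specialists ({erecta, mojavensis}), the endemic {grimshawi}, and
    {sechellia}.  ``MFr`` gives every terminal branch its own class.
    """
    if model_name == "custom":
        if custom_map is None:
            raise ValueError("model 'custom' requires an explicit branch->class map")
        missing = set(tree.branch_ids) - set(custom_map)
        if missing:
            raise ValueError(f"custom map misses branches: {sorted(missing)}")
        return BranchClassLabel(dict(custom_map))
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown branch model {model_name!r}; expected one of {MODEL_NAMES}")

    leaves = set(tree.leaves)
    classes: Dict[str, str] = {}
    if model_name == "MGr":
        for b in tree.branch_ids:
            classes[b] = "all"
    elif model_name == "Mterm":
        for b in tree.branch_ids:
            classes[b] = "terminal" if b in leaves else "internal"
    elif model_name == "MFr":
        for b in tree.branch_ids:
            classes[b] = b if b in leaves else "internal"
    elif model_name == "Mspe-end-sec":
        spe = {"erecta", "mojavensis"}
        for b in tree.branch_ids:
            if b not in leaves:
                classes[b] = "internal"
            elif b in spe:
                classes[b] = "specialist"
            elif b == "grimshawi":
                classes[b] = "endemic"
            elif b == "sechellia":
                classes[b] = "sechellia"
            else:
                classes[b] = "background"
    else:
        fg = set(_FOREGROUND_SETS[model_name])
        missing = fg - leaves
        if missing:
            raise ValueError(f"model {model_name} expects leaves {sorted(missing)} in the tree")
        for b in tree.branch_ids:
            if b not in leaves:
                classes[b] = "internal"
            elif b in fg:
                classes[b] = "foreground"
            else:
                classes[b] = "background"
    return BranchClassLabel(classes)


def model_param_count(tree: DatedTree, model_name: str, equal_rates: bool = False) -> int:
    """Number of free rate parameters: 2 per class (1 if birth = death)."""
    labels = label_branches(tree, model_name)
    return labels.n_classes * (1 if equal_rates else 2)
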