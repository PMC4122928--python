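"""Gene-tree / species-tree reconciliation by LCA mapping.

Each gene-tree node is mapped to the most recent common ancestor of its
descendant species; a node is a duplication iff it maps to the same species
node as one of its children.  Losses are counted per species-tree branch by
the standard path formula: a gene lineage that passes a speciation node
without leaving descendants on one side implies a loss on that side's stem
branch.  Because every OG is assumed present (single copy) at the species
root, a gene-tree root mapping below the root also implies stem losses on
the sister branches of the root path.

Death events of sub-lineages that went fully extinct are invisible here by
construction: this is the mechanism behind the underestimation of turnover
at high rates, and it is deliberately not corrected.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .events import EventMap
from .genetree import GeneNode, GeneTree
from .parsimony import branch_average_rates, global_rates
from .trees import DatedTree

__all__ = [
    "lca_reconcile",
    "apply_conservative_rules",
    "reconcile_rates",
    "CurationOptions",
]


def _species_maps(tree: DatedTree):
    parent = {tree.labels[i]: (tree.labels[tree.parent[i]] if tree.parent[i] != -1 else None)
              for i in range(tree.n_nodes)}
    depth = {tree.labels[i]: tree.depth(i) for i in range(tree.n_nodes)}
    children = {
        tree.labels[i]: [tree.labels[c] for c in tree.children[i]] for i in range(tree.n_nodes)
    }
    return parent, depth, children


def _lca(a: str, b: str, parent, depth) -> str:
    while depth[a] > depth[b]:
        a = parent[a]
    while depth[b] > depth[a]:
        b = parent[b]
    while a != b:
        a, b = parent[a], parent[b]
    return a


def _path_down(top: str, bottom: str, parent) -> List[str]:
    """Species nodes from ``top`` down to ``bottom`` inclusive of both ends."""
    path = [bottom]
    while path[-1] != top:
        nxt = parent[path[-1]]
        if nxt is None:
            raise ValueError(f"{top!r} is not an ancestor of {bottom!r}")
        path.append(nxt)
    return path[::-1]


def lca_reconcile(
    gene_tree: GeneTree,
    tree: DatedTree,
    root_count: int = 1,
    assume_root_presence: bool = True,
) -> Tuple[EventMap, GeneTree]:
    """Map a gene tree into the species tree; infer duplications and losses.

    Returns the per-branch :class:`EventMap` (gains = duplications assigned
    to the branch of their mapped node, losses by the path formula, ``C_i`` =
    gene lineages entering branch ``i``) and the gene tree annotated in
    place with ``mapping`` and ``event`` on every internal node.

    With ``assume_root_presence`` (the default, matching OGs that exist as a
    single copy at the species root), a gene-tree root that maps below the
    species root implies one loss on the stem of each sister clade along the
    root path.  Duplications mapped to the species root itself predate every
    branch and are excluded from the per-branch map.
    """
    parent, depth, children = _species_maps(tree)
    leaves = set(tree.leaves)
    emap = EventMap.zeros(tree)
    bidx = emap._index

    def sibling_on_path(w: str, nxt: str) -> str:
        sibs = [c for c in children[w] if c != nxt]
        if len(sibs) != 1:
            raise ValueError("species tree must be bifurcating")
        return sibs[0]

    def add_path_losses(top: str, bottom: str, include_top: bool) -> None:
        """Losses on sister stems of nodes the lineage passes from top to bottom."""
        path = _path_down(top, bottom, parent)
        passed = path[: -1] if include_top else path[1:-1]
        for w, nxt in zip(path, path[1:]):
            if w in passed:
                emap.L[bidx[sibling_on_path(w, nxt)]] += 1

    # LCA mapping + duplication tagging
    for node in gene_tree.root.postorder():
        if node.is_leaf:
            if node.species not in leaves:
                raise ValueError(f"gene-tree leaf species {node.species!r} not in species tree")
            node.mapping = node.species
        else:
            m = node.children[0].mapping
            for c in node.children[1:]:
                m = _lca(m, c.mapping, parent, depth)
            node.mapping = m
            node.event = (
                "duplication" if any(c.mapping == m for c in node.children) else "speciation"
            )

    root_dups = 0
    for node in gene_tree.root.postorder():
        if node.is_leaf:
            continue
        if node.event == "duplication":
            if node.mapping == tree.root:
                root_dups += 1
            else:
                emap.G[bidx[node.mapping]] += 1
        for c in node.children:
            # duplication: the child lineage also passes the mapped node itself
            add_path_losses(node.mapping, c.mapping, include_top=(node.event == "duplication"))

    if assume_root_presence and gene_tree.root.mapping != tree.root:
        add_path_losses(tree.root, gene_tree.root.mapping, include_top=True)

    # copy number entering each branch, top-down: C_i = copies at parent node
    count_at: Dict[str, int] = {tree.root: root_count + root_dups}
    for i in tree.preorder():
        lab = tree.labels[i]
        if lab == tree.root:
            continue
        k = bidx[lab]
        top = tree.labels[tree.parent[i]]
        if not assume_root_presence and gene_tree.root.mapping != tree.root:
            # lineage only exists below the gene-tree root's mapping
            on_path = _is_descendant(lab, gene_tree.root.mapping, parent)
            if not on_path:
                count_at[lab] = 0
                emap.C[k] = 0
                continue
        emap.C[k] = count_at[top]
        count_at[lab] = count_at[top] + int(emap.G[k]) - int(emap.L[k])
    return emap, gene_tree


def _is_descendant(node: str, anc: str, parent) -> bool:
    while node is not None:
        if node == anc:
            return True
        node = parent[node]
    return False


# ---------------------------------------------------------------------------
# conservative curation rules
# ---------------------------------------------------------------------------


@dataclass
class CurationOptions:
    """Configurable approximations of the manual curation criteria.

    ``unstable_taxa`` are species whose placement is unreliable in gene-tree
    reconstruction (incomplete lineage sorting); when such a species has a
    single copy placed incongruently and a species-congruent regraft implies
    fewer events, the regraft is preferred (down to zero events).
    ``prefer_tip_duplications`` moves non-monophyletic same-species copies
    into a tip clade when that lowers the event count, avoiding
    overestimation of losses from deep duplication placements.
    """

    unstable_taxa: Tuple[str, ...] = ("willistoni", "yakuba", "erecta")
    prefer_tip_duplications: bool = True


def _clone(gt: GeneTree) -> GeneTree:
    return GeneTree(root=copy.deepcopy(gt.root), losses=dict(gt.losses))


def _detach_leaf(root: GeneNode, species: str) -> Tuple[Optional[GeneNode], Optional[GeneNode]]:
    """Remove the single leaf of ``species``; return (new_root, removed_leaf)."""
    removed: List[GeneNode] = []

    def rec(node: GeneNode) -> Optional[GeneNode]:
        if node.is_leaf:
            if node.species == species:
                removed.append(node)
                return None
            return node
        kids = [rec(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node.children = kids
        return node

    new_root = rec(root)
    return new_root, (removed[0] if removed else None)


def _edges_passing(gt: GeneTree, tree: DatedTree, species_node: str) -> List[GeneNode]:
    """Gene nodes whose stem edge passes ``species_node`` in the reconciliation."""
    parent, depth, _ = _species_maps(tree)
    hits: List[GeneNode] = []

    def passes(top: str, bottom: str, include_top: bool) -> bool:
        if not _is_descendant(bottom, species_node, parent):
            return False
        path = _path_down(top, bottom, parent)
        passed = path[:-1] if include_top else path[1:-1]
        return species_node in passed

    stack = [gt.root]
    while stack:
        node = stack.pop()
        for c in node.children:
            if passes(node.mapping, c.mapping, include_top=(node.event == "duplication")):
                hits.append(c)
            if not c.is_leaf:
                stack.append(c)
    # the root stem: lineage from the species root down to the gene root
    if gt.root.mapping != tree.root and passes(tree.root, gt.root.mapping, include_top=True):
        hits.append(gt.root)
    return hits


def _total_events(emap: EventMap) -> int:
    return emap.total_gains() + emap.total_losses()


def apply_conservative_rules(
    gene_tree: GeneTree,
    tree: DatedTree,
    options: Optional[CurationOptions] = None,
) -> EventMap:
    """Reconcile with conservative filters for gene-tree reconstruction error.

    Two configurable rules re-place incongruent genes when doing so lowers
    the implied event count; the reconciliation of the (possibly corrected)
    tree is returned.  Both rules are approximations of case-by-case manual
    curation and are OFF by default in simulation pipelines, where gene
    trees are exact.
    """
    if options is None:
        options = CurationOptions()
    parent, depth, children = _species_maps(tree)

    current = _clone(gene_tree)
    emap, current = lca_reconcile(current, tree)

    # rule 1: single-copy unstable taxa placed incongruently
    for sp in options.unstable_taxa:
        counts = current.leaf_counts()
        if counts.get(sp, 0) != 1:
            continue
        candidate = _clone(current)
        new_root, leaf = _detach_leaf(candidate.root, sp)
        if new_root is None or leaf is None or new_root.is_leaf:
            continue
        pruned = GeneTree(root=new_root)
        _, pruned = lca_reconcile(pruned, tree)
        attach_at = parent[sp]  # species node where the lineage must branch off
        targets = _edges_passing(pruned, tree, attach_at)
        if not targets:
            continue
        target = targets[0]
        fresh_leaf = GeneNode(species=sp, copy_index=1)
        if target is pruned.root:
            regrafted = GeneTree(root=GeneNode(children=[fresh_leaf, pruned.root]))
        else:
            regrafted = GeneTree(root=_regraft_above(pruned.root, target, fresh_leaf))
        new_emap, regrafted = lca_reconcile(regrafted, tree)
        if _total_events(new_emap) < _total_events(emap):
            emap, current = new_emap, regrafted

    # rule 2: prefer tip placements for scattered same-species copies
    if options.prefer_tip_duplications:
        counts = current.leaf_counts()
        for sp, k in counts.items():
            if k < 2 or _species_copies_monophyletic(current, sp):
                continue
            candidate = _collapse_to_tip_clade(current, sp)
            if candidate is None:
                continue
            new_emap, candidate = lca_reconcile(candidate, tree)
            if _total_events(new_emap) < _total_events(emap):
                emap, current = new_emap, candidate
    return emap


def _regraft_above(root: GeneNode, target: GeneNode, leaf: GeneNode) -> GeneNode:
    """Split the edge above ``target`` and attach ``leaf`` as its sister."""

    def rec(node: GeneNode) -> GeneNode:
        kids = []
        for c in node.children:
            if c is target:
                kids.append(GeneNode(children=[leaf, c]))
            else:
                kids.append(rec(c))
        node.children = kids
        return node

    return rec(root)


def _species_copies_monophyletic(gt: GeneTree, species: str) -> bool:
    for node in gt.root.postorder():
        if node.is_leaf:
            continue
        sps = {l.species for l in node.postorder() if l.is_leaf}
        if sps == {species}:
            under = sum(1 for l in node.postorder() if l.is_leaf)
            total = sum(1 for l in gt.leaves() if l.species == species)
            if under == total:
                return True
    total = sum(1 for l in gt.leaves() if l.species == species)
    return total <= 1


def _collapse_to_tip_clade(gt: GeneTree, species: str) -> Optional[GeneTree]:
    """Move all copies of ``species`` into one tip clade at the first copy."""
    candidate = _clone(gt)
    copies = [l for l in candidate.leaves() if l.species == species]
    if len(copies) < 2:
        return None
    keep, extras = copies[0], copies[1:]
    root = candidate.root
    for extra in extras:
        root, _ = _detach_leaf_node(root, extra)
        if root is None:
            return None
    clade = keep
    for i, extra in enumerate(extras):
        clade_new = GeneNode(children=[clade, GeneNode(species=species, copy_index=extra.copy_index)])
        clade = clade_new
    root = _replace_node(root, keep, clade) if clade is not keep else root
    return GeneTree(root=root)


def _detach_leaf_node(root: GeneNode, leaf: GeneNode) -> Tuple[Optional[GeneNode], Optional[GeneNode]]:
    def rec(node: GeneNode) -> Optional[GeneNode]:
        if node is leaf:
            return None
        if node.is_leaf:
            return node
        kids = [rec(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node.children = kids
        return node

    return rec(root), leaf


def _replace_node(root: GeneNode, old: GeneNode, new: GeneNode) -> GeneNode:
    if root is old:
        return new

    def rec(node: GeneNode) -> None:
        for i, c in enumerate(node.children):
            if c is old:
                node.children[i] = new
            else:
                rec(c)

    rec(root)
    return root


# ---------------------------------------------------------------------------
# rates over many gene trees
# ---------------------------------------------------------------------------


def reconcile_rates(
    gene_trees: Sequence[GeneTree],
    tree: DatedTree,
    mode: str = "global",
    curation: Optional[CurationOptions] = None,
) -> Tuple[float, float]:
    """Aggregate reconciliation events over OGs and estimate (beta, delta).

    ``mode`` selects the ratio-of-sums global equations or the branch-average
    form.  ``curation`` (optional) applies the conservative filters to every
    gene tree first; leave it ``None`` for simulated (exact) gene trees.
    """
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    maps: List[EventMap] = []
    for gt in gene_trees:
        if gt is None:
            continue
        if curation is not None:
            maps.append(apply_conservative_rules(gt, tree, curation))
        else:
            emap, _ = lca_reconcile(_clone(gt), tree)
            maps.append(emap)
    if not maps:
        raise ValueError("all gene trees were empty")
    agg = maps[0]
    for e in maps[1:]:
        agg = agg + e
    if mode == "global":
        return global_rates(agg)
    if mode == "branch_average":
        return branch_average_rates(agg)
    raise ValueError(f"unknown mode {mode!r}")
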