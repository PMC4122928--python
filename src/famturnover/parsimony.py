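"""Ancestral family sizes and gain/loss rates from gene-count tables.

Three reconstruction criteria produce per-branch events for each OG:

* Sankoff parsimony (``CSP``): dynamic program over copy-number states with
  linear cost ``|a - b|`` per branch;
* Wagner parsimony (``CWP``): Farris interval method on the ordered integer
  character (optimal cost equal to linear-cost Sankoff);
* ML posterior (``CML``): marginal posterior of each internal node's count
  under fitted birth-death rates, assigned at its mode.

Gains and losses are the one-signed copy-number differences between the
ancestral and derived ends of each branch (a gain and a loss on the same
branch are invisible by construction).  Rates follow either the global
ratio-of-sums form ``beta = sum_i G_i / sum_i C_i T_i`` or the
branch-average form ``beta = mean_i G_i / (C_i T_i)``.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .events import EventMap
from .likelihood import transition_matrix, tree_arrays
from .simulate import BDParams, CountTable
from .trees import BranchClassLabel, DatedTree

__all__ = [
    "sankoff_counts",
    "wagner_counts",
    "ml_ancestral_counts",
    "global_rates",
    "branch_average_rates",
    "apply_pseudogene_mode",
    "events_from_ancestral",
]


def _default_n_max(og_row: Mapping[str, int]) -> int:
    return 2 * max(og_row.values()) + 5


def events_from_ancestral(
    assignment: Mapping[str, int], tree: DatedTree
) -> EventMap:
    """Per-branch events implied by a full ancestral-count assignment.

    ``G_i = max(0, n_child - n_parent)``, ``L_i = max(0, n_parent - n_child)``
    and ``C_i`` is the count at the branch's ancestral node.
    """
    emap = EventMap.zeros(tree)
    for k, b in enumerate(emap.branch_ids):
        i = tree.index[b]
        n_child = assignment[b]
        n_parent = assignment[tree.labels[tree.parent[i]]]
        emap.G[k] = max(0, n_child - n_parent)
        emap.L[k] = max(0, n_parent - n_child)
        emap.C[k] = n_parent
    return emap


# ---------------------------------------------------------------------------
# Sankoff parsimony
# ---------------------------------------------------------------------------


def sankoff_counts(
    og_row: Mapping[str, int], tree: DatedTree, n_max: Optional[int] = None
) -> Tuple[Dict[str, int], EventMap]:
    """Minimum-cost ancestral counts under linear Sankoff parsimony.

    Ties among minimum-cost states are broken by (1) matching the parent's
    assigned value, then (2) the smaller change, then (3) the larger count
    (favouring gains over losses); at the root, by the larger count.
    """
    if n_max is None:
        n_max = _default_n_max(og_row)
    if n_max < max(og_row.values()):
        raise ValueError("n_max below the maximum observed count")
    S = n_max + 1
    states = np.arange(S)
    cost_step = np.abs(states[:, None] - states[None, :]).astype(float)  # |a - b|

    M = tree.n_nodes
    cost = np.zeros((M, S))
    for i in range(M):
        if tree.is_leaf(i):
            obs = og_row[tree.labels[i]]
            cost[i] = np.inf
            cost[i, obs] = 0.0
        else:
            for c in tree.children[i]:
                cost[i] += (cost_step + cost[c][None, :]).min(axis=1)

    assignment: Dict[str, int] = {}
    root = tree.root_index
    best = cost[root].min()
    assignment[tree.labels[root]] = int(np.flatnonzero(cost[root] == best).max())
    for i in tree.preorder():
        if i == root:
            continue
        a = assignment[tree.labels[tree.parent[i]]]
        total = cost_step[a] + cost[i]
        cands = np.flatnonzero(total == total.min())
        # smallest |change| first, then larger count
        d = np.abs(cands - a)
        cands = cands[d == d.min()]
        assignment[tree.labels[i]] = int(cands.max())
    return assignment, events_from_ancestral(assignment, tree)


# ---------------------------------------------------------------------------
# Wagner parsimony
# ---------------------------------------------------------------------------


def wagner_counts(
    og_row: Mapping[str, int], tree: DatedTree
) -> Tuple[Dict[str, int], EventMap]:
    """Farris-interval (Wagner) ancestral counts for the ordered character.

    The down-pass intersects child intervals (or spans the gap between them);
    the up-pass assigns the parent's value when it lies in the node's
    interval and the nearest interval endpoint otherwise.  The root takes the
    smallest value in its final interval.  Total cost equals the linear-cost
    Sankoff optimum.
    """
    M = tree.n_nodes
    lo = np.zeros(M, dtype=np.int64)
    hi = np.zeros(M, dtype=np.int64)
    for i in range(M):
        if tree.is_leaf(i):
            lo[i] = hi[i] = og_row[tree.labels[i]]
        else:
            c1, c2 = tree.children[i]
            a, b = max(lo[c1], lo[c2]), min(hi[c1], hi[c2])
            if a <= b:  # intervals overlap
                lo[i], hi[i] = a, b
            else:  # disjoint: take the gap between them
                lo[i], hi[i] = b, a

    assignment: Dict[str, int] = {}
    root = tree.root_index
    assignment[tree.labels[root]] = int(lo[root])
    for i in tree.preorder():
        if i == root:
            continue
        a = assignment[tree.labels[tree.parent[i]]]
        v = min(max(a, lo[i]), hi[i])  # nearest point of the interval
        assignment[tree.labels[i]] = int(v)
    return assignment, events_from_ancestral(assignment, tree)


# ---------------------------------------------------------------------------
# ML posterior ancestral counts
# ---------------------------------------------------------------------------


def ml_ancestral_counts(
    count_table: CountTable,
    tree: DatedTree,
    labels: BranchClassLabel,
    params: BDParams,
    root_count: int = 1,
    n_max: Optional[int] = None,
) -> List[Tuple[Dict[str, int], EventMap]]:
    """Marginal-posterior ancestral counts per OG under fitted BD rates.

    Inside-outside over the truncated state space with a point-mass root
    prior; each internal node is assigned the posterior mode (ties broken
    toward the smaller count).  Returns one (assignment, EventMap) per OG.
    """
    count_table.validate_against(tree)
    max_obs = int(count_table.counts.to_numpy().max(initial=0))
    if n_max is None:
        n_max = max(2 * max_obs + 5, 10, root_count + 5)
    S = n_max + 1
    arr = tree_arrays(tree)
    M = tree.n_nodes
    root = M - 1

    P = np.zeros((M - 1, S, S))
    for b in range(M - 1):
        beta, delta = params.for_class(labels.classes[tree.labels[b]])
        P[b] = transition_matrix(n_max, arr["T_b"][b], beta, delta)

    out: List[Tuple[Dict[str, int], EventMap]] = []
    leaves = arr["leaves"]
    for og_id in count_table.og_ids:
        row = count_table.row(og_id)
        inside = np.zeros((M, S))
        for i in range(M):
            if arr["child_left"][i] < 0:
                inside[i, row[tree.labels[i]]] = 1.0
            else:
                cl, cr = arr["child_left"][i], arr["child_right"][i]
                inside[i] = (P[cl] @ inside[cl]) * (P[cr] @ inside[cr])
        outside = np.zeros((M, S))
        outside[root, root_count] = 1.0
        for i in tree.preorder():
            if arr["child_left"][i] < 0:
                continue
            cl, cr = arr["child_left"][i], arr["child_right"][i]
            sib_r = P[cr] @ inside[cr]
            sib_l = P[cl] @ inside[cl]
            outside[cl] = (outside[i] * sib_r) @ P[cl]
            outside[cr] = (outside[i] * sib_l) @ P[cr]
        assignment: Dict[str, int] = {}
        for i in range(M):
            lab = tree.labels[i]
            if arr["child_left"][i] < 0:
                assignment[lab] = row[lab]
                continue
            post = outside[i] * inside[i]
            tot = post.sum()
            if not tot > 0:
                raise ValueError(
                    f"unnormalizable posterior for OG {og_id!r} (all-zero likelihood)"
                )
            assignment[lab] = int(np.argmax(post))  # argmax takes smaller index on ties
        out.append((assignment, events_from_ancestral(assignment, tree)))
    return out


# ---------------------------------------------------------------------------
# rates from events
# ---------------------------------------------------------------------------


def _aggregate(events: Union[EventMap, Sequence[EventMap]]) -> EventMap:
    if isinstance(events, EventMap):
        return events
    events = list(events)
    if not events:
        raise ValueError("no EventMaps to aggregate")
    agg = events[0]
    for e in events[1:]:
        agg = agg + e
    return agg


def global_rates(events: Union[EventMap, Sequence[EventMap]]) -> Tuple[float, float]:
    """Ratio-of-sums global rates: ``sum G_i / sum C_i T_i`` (and losses).

    Events per gene per Myr over the whole clade; errors on zero gene-time.
    """
    agg = _aggregate(events)
    denom = agg.gene_time()
    if denom <= 0:
        raise ValueError("zero total gene-time: no gene was at risk on any branch")
    return agg.total_gains() / denom, agg.total_losses() / denom


def branch_average_rates(events: Union[EventMap, Sequence[EventMap]]) -> Tuple[float, float]:
    """Branch-average rates: per-branch quotients ``G_i/(C_i T_i)`` averaged.

    Branches with ``C_i = 0`` carry no gene at risk and are excluded (the
    divisor ``n`` shrinks accordingly); errors if every branch is empty.
    """
    agg = _aggregate(events)
    at_risk = agg.C > 0
    if not at_risk.any():
        raise ValueError("all branches have zero ancestral copies")
    w = (agg.C * agg.T)[at_risk]
    beta = float(np.mean(agg.G[at_risk] / w))
    delta = float(np.mean(agg.L[at_risk] / w))
    return beta, delta


def apply_pseudogene_mode(
    events: EventMap,
    pseudo_counts: Mapping[str, int],
    tree: DatedTree,
    functional_counts: Optional[Mapping[str, int]] = None,
) -> EventMap:
    """Fold annotated pseudogenes into the event counts (psi mode).

    Each pseudogene marks a death on its terminal branch (+1 loss).  It also
    marks the birth of the copy that later pseudogenized (+1 gain on the same
    branch) unless, given ``functional_counts``, the species kept no
    functional copy while other species did -- in which case the pseudogene
    is read as the relic of the ancestral copy and only the loss is counted.
    Both rates are non-decreasing under this mode.
    """
    out = EventMap(
        branch_ids=list(events.branch_ids),
        G=events.G.copy(),
        L=events.L.copy(),
        C=events.C.copy(),
        T=events.T.copy(),
    )
    leaves = set(tree.leaves)
    for sp, npseudo in pseudo_counts.items():
        if npseudo == 0:
            continue
        if sp not in leaves:
            raise ValueError(f"pseudogene species {sp!r} is not a tree leaf")
        k = out._index[sp]
        out.L[k] += npseudo
        relic = False
        if functional_counts is not None:
            others = any(functional_counts.get(s, 0) > 0 for s in leaves if s != sp)
            relic = functional_counts.get(sp, 0) == 0 and others
        ngain = npseudo - 1 if relic else npseudo
        out.G[k] += max(0, ngain)
    return out
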