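"""Exact stochastic simulation of gene-family evolution on a dated tree.

Each orthologous group (OG) starts with ``root_count`` copies at the root and
evolves independently down every branch under a linear birth-death process:
each extant copy duplicates with hazard ``beta`` and dies with hazard
``delta`` (both per gene per Myr, set per branch class).  Zero copies is
absorbing -- new genes arise only by duplication, never by innovation.

Simulation is event-by-event (exponential waiting times) rather than a draw
from the analytic transition kernel, so the realized gains and losses per
branch -- and, in :func:`simulate_gene_tree`, the realized gene tree -- are
available as ground truth for evaluating the estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .events import EventMap
from .genetree import GeneNode, GeneTree
from .trees import BranchClassLabel, DatedTree

__all__ = [
    "BDParams",
    "CountTable",
    "sample_branch_transition",
    "simulate_counts",
    "simulate_gene_tree",
    "derive_seed",
]

RngLike = Union[int, np.random.Generator, np.random.SeedSequence]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def derive_seed(master: int, *key: int) -> np.random.SeedSequence:
    """Deterministic sub-seed for replicate/OG ``key`` under one master seed.

    Any single replicate or OG can be re-run in isolation by passing the same
    master seed and key path.
    """
    return np.random.SeedSequence(entropy=master, spawn_key=tuple(key))


@dataclass
class BDParams:
    """Birth and death rates (events per gene per Myr) for each branch class."""

    rates: Dict[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        for cls, (b, d) in self.rates.items():
            if not (math.isfinite(b) and math.isfinite(d)) or b < 0 or d < 0:
                raise ValueError(f"rates for class {cls!r} must be finite and non-negative")

    @classmethod
    def uniform(cls, beta: float, delta: float, labels: BranchClassLabel) -> "BDParams":
        return cls({c: (beta, delta) for c in labels.class_names()})

    def for_class(self, class_name: str) -> Tuple[float, float]:
        try:
            return self.rates[class_name]
        except KeyError as exc:
            raise KeyError(f"no rates for branch class {class_name!r}") from exc

    def validate_against(self, labels: BranchClassLabel) -> None:
        missing = set(labels.class_names()) - set(self.rates)
        if missing:
            raise ValueError(f"missing rates for branch classes: {sorted(missing)}")


@dataclass
class CountTable:
    """OG x species non-negative integer gene counts (+ optional pseudogenes)."""

    counts: pd.DataFrame
    pseudo: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("gene counts must be non-negative")
        if self.pseudo is not None:
            self.pseudo = self.pseudo.astype(np.int64)
            if list(self.pseudo.columns) != list(self.counts.columns) or list(
                self.pseudo.index
            ) != list(self.counts.index):
                raise ValueError("pseudogene table must align with the count table")
            if (self.pseudo.to_numpy() < 0).any():
                raise ValueError("pseudogene counts must be non-negative")

    @property
    def species(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def og_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def n_og(self) -> int:
        return len(self.counts.index)

    def validate_against(self, tree: DatedTree) -> None:
        if set(self.species) != set(tree.leaves):
            raise ValueError(
                "count-table species do not match tree leaves: "
                f"{sorted(set(self.species) ^ set(tree.leaves))}"
            )

    def totals(self) -> pd.Series:
        """Total gene count per species, summed over OGs."""
        return self.counts.sum(axis=0)

    def row(self, og_id: str) -> Dict[str, int]:
        return {sp: int(v) for sp, v in self.counts.loc[og_id].items()}

    # -- TSV I/O -----------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "OG", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, pseudo_path=None) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        if "OG" not in df.columns:
            raise ValueError("count TSV must have a first column named 'OG'")
        df = df.set_index("OG")
        pseudo = None
        if pseudo_path is not None:
            pseudo = pd.read_csv(pseudo_path, sep="\t").set_index("OG")
        return cls(counts=df, pseudo=pseudo)


# ---------------------------------------------------------------------------
# single-branch transition
# ---------------------------------------------------------------------------


def _branch_events(
    n0: int, t: float, beta: float, delta: float, rng: np.random.Generator
) -> Tuple[int, int, int]:
    """Run the linear BD process for time ``t``; return (n1, births, deaths)."""
    n = n0
    births = deaths = 0
    total_rate = beta + delta
    if total_rate == 0.0 or t == 0.0 or n == 0:
        return n, 0, 0
    clock = 0.0
    pb = beta / total_rate
    while n > 0:
        clock += rng.exponential(1.0 / (n * total_rate))
        if clock >= t:
            break
        if rng.random() < pb:
            n += 1
            births += 1
        else:
            n -= 1
            deaths += 1
    return n, births, deaths


def sample_branch_transition(
    n0: int, t: float, beta: float, delta: float, rng: RngLike
) -> int:
    """Draw the copy number after time ``t`` of a linear BD process at ``n0``.

    Exact event-by-event simulation; ``n0 = 0`` is absorbing.
    """
    if n0 < 0 or t < 0 or beta < 0 or delta < 0:
        raise ValueError("n0, t and rates must be non-negative")
    n1, _, _ = _branch_events(int(n0), float(t), float(beta), float(delta), _as_rng(rng))
    return n1


# ---------------------------------------------------------------------------
# whole-tree count simulation
# ---------------------------------------------------------------------------


def simulate_counts(
    tree: DatedTree,
    labels: BranchClassLabel,
    params: BDParams,
    n_og: int,
    root_count: int = 1,
    rng: RngLike = 0,
    og_prefix: str = "OG",
) -> Tuple[CountTable, List[EventMap]]:
    """Simulate ``n_og`` independent OGs; return leaf counts and true events.

    Every OG starts with ``root_count`` copies at the root; each branch applies
    an independent linear BD transition with its class rates.  The returned
    per-OG :class:`EventMap` records the realized birth and death event counts
    and the copy number at each branch's ancestral node (``n_child = n_parent
    + births - deaths`` holds branch by branch).
    """
    if n_og < 1:
        raise ValueError("n_og must be >= 1")
    params.validate_against(labels)
    missing = set(tree.branch_ids) - set(labels.classes)
    if missing:
        raise ValueError(f"unlabeled branches: {sorted(missing)}")
    generator = _as_rng(rng)

    branch_ids = tree.branch_ids
    T = np.array([tree.branch_duration(b) for b in branch_ids])
    leaf_names = tree.leaves

    rows = np.zeros((n_og, len(leaf_names)), dtype=np.int64)
    leaf_pos = {sp: j for j, sp in enumerate(leaf_names)}
    event_maps: List[EventMap] = []

    preorder = tree.preorder()
    root = tree.root_index
    bindex = {b: i for i, b in enumerate(branch_ids)}

    for og in range(n_og):
        node_count = np.zeros(tree.n_nodes, dtype=np.int64)
        node_count[root] = root_count
        G = np.zeros(len(branch_ids), dtype=np.int64)
        L = np.zeros(len(branch_ids), dtype=np.int64)
        C = np.zeros(len(branch_ids), dtype=np.int64)
        for i in preorder:
            if i == root:
                continue
            lab = tree.labels[i]
            beta, delta = params.for_class(labels.classes[lab])
            n_parent = int(node_count[tree.parent[i]])
            n1, births, deaths = _branch_events(
                n_parent, tree.duration[i], beta, delta, generator
            )
            node_count[i] = n1
            k = bindex[lab]
            G[k], L[k], C[k] = births, deaths, n_parent
        for sp, j in leaf_pos.items():
            rows[og, j] = node_count[tree.index[sp]]
        event_maps.append(EventMap(branch_ids=list(branch_ids), G=G, L=L, C=C, T=T.copy()))

    df = pd.DataFrame(
        rows,
        index=[f"{og_prefix}{i + 1}" for i in range(n_og)],
        columns=leaf_names,
    )
    df.index.name = "OG"
    return CountTable(counts=df), event_maps


# ---------------------------------------------------------------------------
# gene-tree simulation
# ---------------------------------------------------------------------------


def simulate_gene_tree(
    tree: DatedTree,
    labels: BranchClassLabel,
    params: BDParams,
    rng: RngLike = 0,
) -> Tuple[Optional[GeneTree], EventMap]:
    """Simulate one OG recording the realized gene tree of surviving copies.

    Starts from a single copy at the root.  Each birth bifurcates the gene
    lineage at its event time (a duplication node); each death prunes it.
    Lineages split at every speciation node.  Returns the pruned gene tree
    (``None`` when the whole family went extinct) together with the true
    per-branch :class:`EventMap`; death events of fully extinct sub-lineages
    are present in the EventMap but invisible in the gene tree -- exactly the
    information loss that reconciliation-based estimators face.
    """
    params.validate_against(labels)
    generator = _as_rng(rng)

    branch_ids = tree.branch_ids
    bindex = {b: i for i, b in enumerate(branch_ids)}
    T = np.array([tree.branch_duration(b) for b in branch_ids])
    G = np.zeros(len(branch_ids), dtype=np.int64)
    L = np.zeros(len(branch_ids), dtype=np.int64)
    C = np.zeros(len(branch_ids), dtype=np.int64)
    entering = np.zeros(len(branch_ids), dtype=np.int64)
    copy_counter: Dict[str, int] = {}

    def evolve_on_branch(node_idx: int, t_remaining: float) -> Optional[GeneNode]:
        """One gene lineage on the branch above species node ``node_idx``."""
        lab = tree.labels[node_idx]
        beta, delta = params.for_class(labels.classes[lab])
        k = bindex[lab]
        total = beta + delta
        while True:
            if total > 0:
                wait = generator.exponential(1.0 / total)
            else:
                wait = math.inf
            if wait >= t_remaining:
                break
            t_remaining -= wait
            if generator.random() < (beta / total):
                G[k] += 1
                left = evolve_on_branch(node_idx, t_remaining)
                right = evolve_on_branch(node_idx, t_remaining)
                if left is None and right is None:
                    return None
                if left is None:
                    return right
                if right is None:
                    return left
                return GeneNode(children=[left, right], event="duplication")
            L[k] += 1
            return None
        return at_species_node(node_idx)

    def at_species_node(node_idx: int) -> Optional[GeneNode]:
        """Lineage reaches species node ``node_idx`` alive."""
        if tree.is_leaf(node_idx):
            sp = tree.labels[node_idx]
            copy_counter[sp] = copy_counter.get(sp, 0) + 1
            return GeneNode(species=sp, copy_index=copy_counter[sp])
        kids = []
        for c in tree.children[node_idx]:
            entering[bindex[tree.labels[c]]] += 1
            kids.append(evolve_on_branch(c, tree.duration[c]))
        alive = [x for x in kids if x is not None]
        if not alive:
            return None
        if len(alive) == 1:
            return alive[0]
        return GeneNode(children=alive, event="speciation")

    root_node = at_species_node(tree.root_index)
    C[:] = entering
    emap = EventMap(branch_ids=list(branch_ids), G=G, L=L, C=C, T=T)
    if root_node is None:
        return None, emap
    gt = GeneTree(
        root=root_node,
        losses={b: int(L[bindex[b]]) for b in branch_ids if L[bindex[b]] > 0},
    )
    return gt, emap
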