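import pytest

from famturnover.trees import DatedTree, fixture_drosophila_tree, parse_dated_newick


@pytest.fixture(scope="session")
def drosophila_tree() -> DatedTree:
    return fixture_drosophila_tree()


@pytest.fixture(scope="session")
def tree3() -> DatedTree:
    """Three-taxon tree with unequal depths per clade but ultrametric overall."""
    return parse_dated_newick("((A:1,B:1)ab:1,C:2)r;")


@pytest.fixture(scope="session")
def tree5() -> DatedTree:
    return parse_dated_newick("(((A:1,B:1)ab:1,(C:1,D:1)cd:1)abcd:1,E:3)r;")


@pytest.fixture(scope="session")
def tree6() -> DatedTree:
    return parse_dated_newick("((((A:1,B:1)ab:1,C:2)abc:1,(D:2,E:2)de:1)abcde:1,F:4)r;")


def exhaustive_min_linear_cost(tree: DatedTree, og_row, max_state: int) -> int:
    """Brute-force minimum total |change| over all ancestral assignments.

    Independent oracle for the parsimony reconstructions: enumerates every
    assignment of states 0..max_state to the internal nodes.
    """
    import itertools

    internals = [lab for lab in tree.labels if lab not in tree.leaves]
    best = None
    for assign in itertools.product(range(max_state + 1), repeat=len(internals)):
        full = dict(og_row)
        full.update(dict(zip(internals, assign)))
        cost = 0
        for i in range(tree.n_nodes):
            if tree.parent[i] == -1:
                continue
            cost += abs(full[tree.labels[i]] - full[tree.labels[tree.parent[i]]])
        if best is None or cost < best:
            best = cost
    return best
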