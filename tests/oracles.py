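"""Independent oracles used by the test suite.

These deliberately avoid the package's own traversal code: the permutation
oracle filters every ordered node tuple, the networkx oracle relies on
``networkx.all_simple_paths`` over an equivalent digraph.  Both operate on
gene sequences, assuming at most one link per unordered gene pair (true for
all generated test graphs).
"""

from itertools import permutations

import networkx as nx


def _traversable(network, a, b):
    ln = network.find_link(a, b)
    if ln is None:
        return False
    return (not ln.directed) or (ln.source, ln.target) == (a, b)


def _all_undirected(network, path):
    return all(not network.find_link(a, b).directed for a, b in zip(path, path[1:]))


def dedup(network, paths, start_set, end_set):
    """Apply the once-per-canonical-form rule to a set of gene sequences."""
    start_set, end_set = set(start_set), set(end_set)
    out = set()
    for p in paths:
        rev = tuple(reversed(p))
        if (
            _all_undirected(network, p)
            and rev != p
            and rev[0] in start_set
            and rev[-1] in end_set
            and rev < p
        ):
            continue  # the reverse orientation represents this pathway
        out.add(p)
    return out


def perm_simple_paths(network, start_set, end_set, max_links):
    """Brute force over all ordered node tuples (use only for tiny graphs)."""
    nodes = network.genes
    found = set()
    for k in range(2, max_links + 2):
        for perm in permutations(nodes, k):
            if perm[0] not in start_set or perm[-1] not in end_set:
                continue
            if all(_traversable(network, a, b) for a, b in zip(perm, perm[1:])):
                found.add(perm)
    return dedup(network, found, start_set, end_set)


def nx_simple_paths(network, start_set, end_set, max_links):
    """networkx-based oracle: all simple paths on the traversal digraph."""
    G = nx.DiGraph()
    G.add_nodes_from(network.genes)
    for ln in network.links:
        G.add_edge(ln.source, ln.target)
        if not ln.directed:
            G.add_edge(ln.target, ln.source)
    found = set()
    ends = set(end_set) & set(network.genes)
    for s in set(start_set) & set(network.genes):
        targets = ends - {s}
        if targets:
            for path in nx.all_simple_paths(G, s, targets, cutoff=max_links):
                found.add(tuple(path))
    return dedup(network, found, start_set, end_set)


def random_test_network(rng, n, edge_prob, frac_directed, frac_inhibition):
    """Random graph with at most one link per unordered pair."""
    from actichain.network import FunctionalNetwork, Link

    genes = [f"n{i:02d}" for i in range(n)]
    net = FunctionalNetwork(genes=genes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                a, b = genes[i], genes[j]
                if rng.random() < 0.5:
                    a, b = b, a
                directed = bool(rng.random() < frac_directed)
                sign = "inhibition" if rng.random() < frac_inhibition else (
                    "stimulation" if directed else "interaction"
                )
                net.add_link(Link(a, b, directed=directed, sign=sign))
    return net
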