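"""Shared fixtures and independent oracles for the test suite.

The oracles here re-derive the walk quantities straight from their
definitions (explicit walk enumeration, plain matrix powers) so the package
implementation is checked against code that shares none of its shortcuts.
"""

from __future__ import annotations

import numpy as np
import pytest

from pathrewire.network import WeightedNetwork


# ---------------------------------------------------------------------------
# graph fixtures


@pytest.fixture
def path_network() -> WeightedNetwork:
    """A - B - C with uniform weights; the closed-form workhorse."""
    return WeightedNetwork(
        nodes=("A", "B", "C"),
        edges=(("A", "B"), ("B", "C")),
        edge_weights=np.array([0.5, 0.5]),
    )


@pytest.fixture
def cycle_network() -> WeightedNetwork:
    """4-node cycle with asymmetric weights."""
    return WeightedNetwork(
        nodes=("A", "B", "C", "D"),
        edges=(("A", "B"), ("A", "D"), ("B", "C"), ("C", "D")),
        edge_weights=np.array([0.9, 0.2, 0.4, 0.7]),
    )


def random_network(
    rng: np.random.Generator, n_nodes: int, n_edges: int, connected: bool = True
) -> WeightedNetwork:
    """Random weighted graph with distinct node names, weights in (0.05, 1]."""
    names = tuple(chr(ord("A") + i) if n_nodes <= 26 else f"N{i:02d}" for i in range(n_nodes))
    all_pairs = [(names[i], names[j]) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    while True:
        k = min(n_edges, len(all_pairs))
        idx = rng.choice(len(all_pairs), size=k, replace=False)
        edges = sorted(all_pairs[i] for i in idx)
        if connected:
            # union-find connectivity check
            parent = {g: g for g in names}

            def find(a):
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            for a, b in edges:
                parent[find(a)] = find(b)
            if len({find(g) for g in names}) > 1:
                continue
        weights = rng.uniform(0.05, 1.0, size=len(edges))
        return WeightedNetwork(nodes=names, edges=tuple(edges), edge_weights=weights)


# ---------------------------------------------------------------------------
# oracle 1: explicit enumeration of all absorbed walks (tiny graphs)


def enumerate_absorbed_walks(network: WeightedNetwork, seed_set, start, l_max):
    """Enumerate every walk from ``start`` absorbed in S \\ {start} within l_max.

    Returns (pL, per_L) where pL[L-1] = P[L | X0 = x] and per_L[L] maps
    directed node-index pairs to sum over length-L walks of prob * count.
    Derived directly from the walk definition, independent of any matrix
    algebra.
    """
    from pathrewire.kwalk import transition_probabilities

    P = transition_probabilities(network)
    idx = {g: network.node_index(g) for g in network.nodes}
    absorbing = {idx[g] for g in seed_set if g != start}
    pL = np.zeros(l_max)
    per_L: dict[int, dict[tuple[int, int], float]] = {L: {} for L in range(1, l_max + 1)}

    def dfs(state: int, prob: float, length: int, counts: dict):
        for j in range(network.n_nodes):
            p_step = P[state, j]
            if p_step == 0.0:
                continue
            new_prob = prob * p_step
            edge = (state, j)
            counts[edge] = counts.get(edge, 0) + 1
            if j in absorbing:
                L = length + 1
                pL[L - 1] += new_prob
                acc = per_L[L]
                for e, c in counts.items():
                    acc[e] = acc.get(e, 0.0) + new_prob * c
            elif length + 1 < l_max:
                dfs(j, new_prob, length + 1, counts)
            counts[edge] -= 1
            if counts[edge] == 0:
                del counts[edge]

    dfs(idx[start], 1.0, 0, {})
    return pL, per_L


def enumerated_passages(network, seed_set, start, l_max, mode):
    """Aggregate the enumeration oracle the way each mode prescribes."""
    pL, per_L = enumerate_absorbed_walks(network, seed_set, start, l_max)
    n = network.n_nodes
    E = np.zeros((n, n))
    if mode == "weighted":
        mass = pL.sum()
        for L in range(1, l_max + 1):
            for (i, j), v in per_L[L].items():
                E[i, j] += v
        E /= mass
    else:
        for L in range(1, l_max + 1):
            if pL[L - 1] <= 0.0:
                continue
            for (i, j), v in per_L[L].items():
                E[i, j] += v / pL[L - 1]
    return E


# ---------------------------------------------------------------------------
# oracle 2: plain matrix-power transcription of the defining equations


def direct_form_passages(network: WeightedNetwork, seed_set, start, l_max, mode):
    """Expected passages computed with literal matrix powers.

    Transcribes the transient/absorbing block formulas term by term:
    per-(L, k) joint probabilities summed over absorbing targets, conditional
    expectation per L, then the mode's aggregation. No recursions shared with
    the package implementation.
    """
    from pathrewire.kwalk import transition_probabilities

    P = transition_probabilities(network)
    idx = {g: network.node_index(g) for g in network.nodes}
    absorbing = sorted(idx[g] for g in seed_set if g != start)
    transient = [i for i in range(network.n_nodes) if i not in set(absorbing)]
    Q = P[np.ix_(transient, transient)]
    R = P[np.ix_(transient, absorbing)]
    x = transient.index(idx[start])
    t = len(transient)
    Qp = [np.linalg.matrix_power(Q, k) for k in range(l_max + 1)]

    def joint(L):
        """J[i, j] = P[cross (i, j) at some step, total length L | X0=x]."""
        Jt = np.zeros((t, t))
        for k in range(0, L - 1):
            tail = (Qp[L - k - 2] @ R).sum(axis=1)  # sum over absorbing r
            Jt += np.outer(Qp[k][x, :], tail) * Q  # Q[i,j] factor elementwise
        Ja = np.outer(Qp[L - 1][x, :], np.ones(len(absorbing))) * R
        return Jt, Ja

    pL = np.array([(Qp[L - 1] @ R)[x, :].sum() for L in range(1, l_max + 1)])
    Et = np.zeros((t, t))
    Ea = np.zeros((t, len(absorbing)))
    if mode == "weighted":
        mass = pL.sum()
        for L in range(1, l_max + 1):
            Jt, Ja = joint(L)
            Et += Jt
            Ea += Ja
        Et /= mass
        Ea /= mass
    else:
        for L in range(1, l_max + 1):
            if pL[L - 1] <= 0.0:
                continue
            Jt, Ja = joint(L)
            Et += Jt / pL[L - 1]
            Ea += Ja / pL[L - 1]
    n = network.n_nodes
    E = np.zeros((n, n))
    E[np.ix_(transient, transient)] = Et
    E[np.ix_(transient, absorbing)] = Ea
    return E


def direct_form_edge_relevance(network, seed_set, l_max, mode="weighted"):
    """ER from the direct-form oracle with uniform start weights."""
    seeds = sorted(seed_set)
    n = network.n_nodes
    flow = np.zeros((n, n))
    for x in seeds:
        E = direct_form_passages(network, seed_set, x, l_max, mode)
        flow += np.abs(E - E.T) / len(seeds)
    return {
        (a, b): flow[network.node_index(a), network.node_index(b)]
        for a, b in network.edges
    }


# ---------------------------------------------------------------------------
# oracle 3: exhaustive threshold enumeration


def brute_force_threshold(relevance: dict, seeds) -> float | None:
    """Try every distinct positive ER value; return the largest that connects."""
    import networkx as nx

    seeds = sorted(set(seeds))
    best = None
    for theta in sorted({er for er in relevance.values() if er > 0.0}):
        g = nx.Graph(e for e, er in relevance.items() if er >= theta and er > 0.0)
        g.add_nodes_from(seeds)
        root = seeds[0]
        comp = nx.node_connected_component(g, root)
        if all(s in comp for s in seeds):
            best = theta if best is None else max(best, theta)
    return best
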