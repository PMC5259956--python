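"""Limited k-walks edge relevance via absorbing Markov chains.

Given a weighted network and a seed gene set S (|S| >= 2), a random walk is
started from each seed x; the remaining seeds S \\ {x} are made absorbing.
For every directed edge the expected number of traversals by a walk absorbed
within L_max steps is computed exactly from the transient/absorbing block
decomposition of the transition matrix:

    P_ij = a_ij / d_i                           (row-normalized weights)
    xP   = [[Q, R], [0, I]]                     (transient / absorbing blocks)

The per-length joint probability of crossing edge (i, j) at step k of a walk
of total length L is

    [Q^k]_{x i} Q_{ij} [Q^{L-k-2} R 1]_j        (j transient, 0 <= k <= L-2)
    [Q^{L-1}]_{x i} R_{ij}                      (j absorbing, k = L-1)

and P[L | X0 = x] = [Q^{L-1} R 1]_x. Two aggregations over L are offered:

``weighted`` (default)
    E[e(x,i,j) | L <= L_max], the conditional expectation given absorption
    within L_max steps: sum of joint probabilities over all (L, k) divided by
    the total absorption mass. This is the quantity a Monte-Carlo simulation
    of absorbed walks estimates.
``literal``
    sum_{L=1}^{L_max} E[e(x,i,j) | L], the plain sum of per-length
    conditional expectations (each defined as 0 where P[L] = 0). This form
    grows with L_max and weights every feasible length equally.

The edge relevance of an undirected edge is the start-weighted absolute net
flow

    ER(i,j) = sum_{x in S} l_x | E[e(x,i,j)] - E[e(x,j,i)] |

with l the initial start distribution over S (uniform by default). Starts
whose absorption mass within L_max is negligible are skipped and l is
renormalized over the remaining starts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import WeightedNetwork

logger = logging.getLogger(__name__)

#: Starts with absorption mass <= this within L_max are skipped.
DEFAULT_MASS_EPS = 1e-12

#: Default maximal walk length.
DEFAULT_L_MAX = 50


class NegligibleAbsorption(RuntimeError):
    """The start's probability of absorption within L_max is ~ 0."""


def transition_probabilities(network: WeightedNetwork) -> np.ndarray:
    """Row-stochastic transition matrix P_ij = a_ij / d_i.

    Rows of zero-degree (isolated) nodes are all-zero; such nodes are logged
    as unreachable-from.
    """
    A = network.adjacency()
    d = A.sum(axis=1)
    zero = d == 0.0
    if zero.any():
        logger.debug("%d zero-degree nodes have all-zero transition rows", int(zero.sum()))
    safe = np.where(zero, 1.0, d)
    P = A / safe[:, None]
    P[zero] = 0.0
    return P


@dataclass
class AbsorbingWalkProblem:
    """One start of the absorbing walk: start x in S, absorbing set S \\ {x}."""

    network: WeightedNetwork
    seed_set: frozenset[str]
    start: str
    l_max: int = DEFAULT_L_MAX

    def __post_init__(self) -> None:
        self.seed_set = frozenset(self.seed_set)
        if len(self.seed_set) < 2:
            raise ValueError("seed set must contain at least 2 genes")
        if self.start not in self.seed_set:
            raise ValueError(f"start {self.start!r} not in seed set")
        unknown = [g for g in self.seed_set if g not in self.network]
        if unknown:
            raise ValueError(f"seed genes absent from network: {sorted(unknown)}")
        if self.l_max < 1:
            raise ValueError("l_max must be >= 1")

    @property
    def absorbing(self) -> frozenset[str]:
        return self.seed_set - {self.start}


@dataclass
class _Chain:
    """Index bookkeeping plus the Q/R blocks for one start."""

    transient: np.ndarray  # node indices, network order
    absorbing: np.ndarray
    x_pos: int  # position of the start within the transient ordering
    Q: np.ndarray  # (t, t)
    R: np.ndarray  # (t, a)


def _build_chain(problem: AbsorbingWalkProblem) -> _Chain:
    net = problem.network
    P = transition_probabilities(net)
    absorbing_idx = np.array(sorted(net.node_index(g) for g in problem.absorbing), dtype=int)
    mask = np.ones(net.n_nodes, dtype=bool)
    mask[absorbing_idx] = False
    transient_idx = np.flatnonzero(mask)
    x_pos = int(np.searchsorted(transient_idx, net.node_index(problem.start)))
    Q = P[np.ix_(transient_idx, transient_idx)]
    R = P[np.ix_(transient_idx, absorbing_idx)]
    return _Chain(transient=transient_idx, absorbing=absorbing_idx, x_pos=x_pos, Q=Q, R=R)


def _forward_rows(chain: _Chain, l_max: int) -> np.ndarray:
    """a_k = e_x Q^k for k = 0 .. l_max-1, stacked as rows."""
    t = chain.Q.shape[0]
    a = np.zeros((l_max, t))
    a[0, chain.x_pos] = 1.0
    for k in range(1, l_max):
        a[k] = a[k - 1] @ chain.Q
    return a


def _backward_columns(chain: _Chain, l_max: int) -> np.ndarray:
    """b_m = Q^m R 1 for m = 0 .. l_max-2: absorption in exactly m+1 steps."""
    t = chain.Q.shape[0]
    n_rows = max(l_max - 1, 1)
    b = np.zeros((n_rows, t))
    b[0] = chain.R.sum(axis=1)
    for m in range(1, l_max - 1):
        b[m] = chain.Q @ b[m - 1]
    return b


def absorbed_length_distribution(
    problem: AbsorbingWalkProblem,
) -> tuple[np.ndarray, float]:
    """P[L | X0 = x] for L = 1 .. L_max, plus the total mass P[L <= L_max].

    Returned array has ``pL[L-1] = P[L | X0 = x]``.
    """
    chain = _build_chain(problem)
    a = _forward_rows(chain, problem.l_max)
    rsum = chain.R.sum(axis=1)
    pL = a @ rsum
    return pL, float(pL.sum())


def expected_edge_passages(
    problem: AbsorbingWalkProblem,
    mode: str = "weighted",
    mass_eps: float = DEFAULT_MASS_EPS,
) -> np.ndarray:
    """Expected directed edge passages for walks absorbed within L_max.

    Returns an (n, n) matrix in network node order; entry (i, j) is the
    aggregated expectation of traversals of the directed edge i -> j (see
    module docstring for the two aggregation modes). Rows of absorbing nodes
    are zero (an absorbed walk never leaves).

    Raises :class:`NegligibleAbsorption` when P[L <= L_max] <= ``mass_eps``.
    """
    if mode not in ("weighted", "literal"):
        raise ValueError(f"mode must be 'weighted' or 'literal', got {mode!r}")
    chain = _build_chain(problem)
    l_max = problem.l_max
    a = _forward_rows(chain, l_max)
    rsum = chain.R.sum(axis=1)
    pL = a @ rsum
    mass = float(pL.sum())
    if mass <= mass_eps:
        raise NegligibleAbsorption(
            f"start {problem.start!r}: absorption mass {mass:.3g} <= {mass_eps:.3g} "
            f"within L_max={l_max}"
        )
    b = _backward_columns(chain, l_max)

    t = chain.Q.shape[0]
    if mode == "weighted":
        # Sum of joint probabilities over all (L, k), then divide by the mass:
        # transient branch collapses to a convolution of forward and
        # cumulative-backward vectors.
        C = np.zeros((t, t))
        if l_max >= 2:
            Bcum = np.cumsum(b[: l_max - 1], axis=0)  # Bcum[M] = sum_{m<=M} b_m
            for k in range(l_max - 1):
                C += np.outer(a[k], Bcum[l_max - 2 - k])
        E_trans = chain.Q * C / mass
        E_abs = (a.sum(axis=0)[:, None] * chain.R) / mass
    else:
        E_trans = np.zeros((t, t))
        E_abs = np.zeros((t, chain.R.shape[1]))
        for L in range(1, l_max + 1):
            p = float(pL[L - 1])
            if p <= 0.0:
                continue  # E[e | L] defined as 0 when P[L] = 0
            joint_abs = a[L - 1][:, None] * chain.R
            if L >= 2:
                C = np.zeros((t, t))
                for k in range(L - 1):
                    C += np.outer(a[k], b[L - 2 - k])
                E_trans += chain.Q * C / p
            E_abs += joint_abs / p

    n = problem.network.n_nodes
    E = np.zeros((n, n))
    E[np.ix_(chain.transient, chain.transient)] = E_trans
    E[np.ix_(chain.transient, chain.absorbing)] = E_abs
    return E


@dataclass
class EdgeRelevanceMap:
    """Per-undirected-edge relevance scores for one seed set in one network."""

    relevance: dict[tuple[str, str], float]
    start_weights: dict[str, float]
    mode: str
    skipped_starts: tuple[str, ...] = ()
    seed_set: frozenset[str] = field(default_factory=frozenset)

    def __getitem__(self, edge: tuple[str, str]) -> float:
        a, b = edge
        return self.relevance[(a, b) if a < b else (b, a)]

    @property
    def effective_seeds(self) -> frozenset[str]:
        """Seeds that actually contributed as walk starts."""
        return self.seed_set - set(self.skipped_starts)

    def write_edge_list(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\tER\n")
            for (a, b), er in sorted(self.relevance.items()):
                fh.write(f"{a}\t{b}\t{er:.10g}\n")


def edge_relevance(
    network: WeightedNetwork,
    seed_set: frozenset[str] | set[str],
    l_max: int = DEFAULT_L_MAX,
    start_weights: dict[str, float] | None = None,
    mode: str = "weighted",
    mass_eps: float = DEFAULT_MASS_EPS,
) -> EdgeRelevanceMap:
    """Start-weighted absolute net expected passage per undirected edge.

    ``start_weights`` is the initial distribution l over the seeds (uniform
    by default). Starts with negligible absorption mass within ``l_max`` are
    skipped and l is renormalized over the remaining starts; if every start
    is skipped a :class:`NegligibleAbsorption` is raised.
    """
    seed_set = frozenset(seed_set)
    if len(seed_set) < 2:
        raise ValueError("edge relevance requires a seed set with |S| >= 2")
    if start_weights is None:
        start_weights = {x: 1.0 / len(seed_set) for x in seed_set}
    else:
        missing = seed_set - set(start_weights)
        if missing:
            raise ValueError(f"start_weights missing seeds: {sorted(missing)}")

    n = network.n_nodes
    net_flow = np.zeros((n, n))
    skipped: list[str] = []
    contributions: list[tuple[str, np.ndarray]] = []
    for x in sorted(seed_set):
        problem = AbsorbingWalkProblem(network=network, seed_set=seed_set, start=x, l_max=l_max)
        try:
            E = expected_edge_passages(problem, mode=mode, mass_eps=mass_eps)
        except NegligibleAbsorption:
            skipped.append(x)
            continue
        contributions.append((x, np.abs(E - E.T)))
    if not contributions:
        raise NegligibleAbsorption(
            f"every start in {sorted(seed_set)} has negligible absorption mass"
        )
    if skipped:
        logger.info(
            "skipped %d/%d walk starts with negligible absorption: %s",
            len(skipped),
            len(seed_set),
            skipped,
        )
    total_l = sum(start_weights[x] for x, _ in contributions)
    if total_l <= 0:
        raise ValueError("start weights over reachable starts sum to 0")
    used_weights = {x: start_weights[x] / total_l for x, _ in contributions}
    for x, flow in contributions:
        net_flow += used_weights[x] * flow

    relevance = {
        (u, v): float(net_flow[network.node_index(u), network.node_index(v)])
        for u, v in network.edges
    }
    return EdgeRelevanceMap(
        relevance=relevance,
        start_weights=used_weights,
        mode=mode,
        skipped_starts=tuple(skipped),
        seed_set=seed_set,
    )


def simulate_walks(
    problem: AbsorbingWalkProblem, n_walks: int, seed: int
) -> dict:
    """Monte-Carlo estimate of the absorbed-walk edge passage expectations.

    Simulates ``n_walks`` random walks from the start under the absorbing
    dynamics, discards walks not absorbed within L_max, and returns the
    empirical conditional expectations with standard errors. Intended as an
    independent check of :func:`expected_edge_passages` (weighted mode).

    Returns a dict with keys ``mean`` (n x n empirical E[e(x,i,j)|L<=L_max]),
    ``se`` (standard errors), ``pL`` (empirical length distribution over
    1..L_max normalized by total walks), ``n_absorbed``.
    """
    if n_walks < 1:
        raise ValueError("n_walks must be >= 1")
    net = problem.network
    n = net.n_nodes
    if n > 64:
        raise ValueError("simulate_walks is a verification oracle for small graphs (n <= 64)")
    rng = np.random.default_rng(seed)
    P = transition_probabilities(net)
    cum = np.cumsum(P, axis=1)
    row_tot = cum[:, -1].copy()
    absorbing = np.array(sorted(net.node_index(g) for g in problem.absorbing), dtype=int)
    is_absorbing = np.zeros(n, dtype=bool)
    is_absorbing[absorbing] = True
    x = net.node_index(problem.start)

    count_dtype = np.uint8 if problem.l_max <= 255 else np.uint16
    counts = np.zeros((n_walks, n, n), dtype=count_dtype)
    lengths = np.zeros(n_walks, dtype=int)
    absorbed = np.zeros(n_walks, dtype=bool)
    current = np.full(n_walks, x, dtype=int)
    active = np.ones(n_walks, dtype=bool)
    # zero-degree states can never move: such walks simply stay unabsorbed
    stuck = row_tot[current] == 0.0
    active &= ~stuck
    for step in range(1, problem.l_max + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        cur = current[idx]
        u = rng.random(idx.size) * row_tot[cur]
        nxt = (cum[cur] < u[:, None]).sum(axis=1)
        counts[idx, cur, nxt] += 1
        lengths[idx] = step
        current[idx] = nxt
        hit = is_absorbing[nxt]
        absorbed[idx[hit]] = True
        active[idx[hit]] = False
        stuck = row_tot[nxt] == 0.0
        active[idx[~hit & stuck]] = False

    n_abs = int(absorbed.sum())
    if n_abs == 0:
        raise RuntimeError("no walk was absorbed within L_max; cannot estimate")
    kept = counts[absorbed].astype(float)
    mean = kept.mean(axis=0)
    se = kept.std(axis=0, ddof=1) / np.sqrt(n_abs) if n_abs > 1 else np.full((n, n), np.inf)
    pL = np.zeros(problem.l_max)
    for L, c in zip(*np.unique(lengths[absorbed], return_counts=True)):
        pL[L - 1] = c / n_walks
    return {"mean": mean, "se": se, "pL": pL, "n_absorbed": n_abs}
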