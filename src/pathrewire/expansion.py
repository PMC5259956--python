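"""Pathway expansion: threshold an edge-relevance map into a subnetwork.

The expansion keeps the edges whose relevance is at least theta, where theta
is the *largest* realized relevance value that still leaves all (reachable)
seed genes in one connected component. The expanded genes are the non-seed
endpoints of the kept edges. The cross-phenotype union of the two expanded
subnetworks is the domain on which a pathway is scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import GeneSetCollection
from .kwalk import DEFAULT_L_MAX, EdgeRelevanceMap, NegligibleAbsorption, edge_relevance
from .network import WeightedNetwork

logger = logging.getLogger(__name__)

SKIP_LT2_SEED = "skipped_lt2_seed"
SKIP_UNCONNECTABLE = "skipped_unconnectable"


class SeedsNotConnectable(RuntimeError):
    """No positive-relevance threshold places all seeds in one component."""


def map_seed(
    pathway_genes, network: WeightedNetwork
) -> tuple[frozenset[str], str | None]:
    """Intersect a pathway's gene list with the network nodes.

    Returns ``(seed_set, skip_reason)``; ``skip_reason`` is
    ``"skipped_lt2_seed"`` when fewer than two genes map (a single-gene seed
    cannot define an absorbing walk), else ``None``.
    """
    seeds = frozenset(g for g in pathway_genes if g in network)
    if len(seeds) < 2:
        return seeds, SKIP_LT2_SEED
    return seeds, None


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, a):
        p = self.parent.setdefault(a, a)
        while p != self.parent[p]:
            self.parent[p] = self.parent[self.parent[p]]
            p = self.parent[p]
        self.parent[a] = p
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def select_threshold(
    relevance: EdgeRelevanceMap, seed_set: frozenset[str] | set[str]
) -> float:
    """Largest realized positive ER value whose >=-cut connects the seeds.

    Scans distinct positive relevance values in descending order, adding
    edge groups of equal value, until every seed shares one connected
    component; the value of the last group added is theta. Raises
    :class:`SeedsNotConnectable` when even the full positive-relevance
    subgraph leaves the seeds apart.
    """
    seeds = sorted(set(seed_set))
    if not seeds:
        raise ValueError("empty seed set")
    positive = [(er, e) for e, er in relevance.relevance.items() if er > 0.0]
    if not positive:
        raise SeedsNotConnectable("no edge has positive relevance")
    positive.sort(key=lambda t: (-t[0], t[1]))

    uf = _UnionFind()
    for s in seeds:
        uf.find(s)

    def seeds_connected() -> bool:
        root = uf.find(seeds[0])
        return all(uf.find(s) == root for s in seeds[1:])

    if len(seeds) == 1:
        return positive[0][0]

    i = 0
    n = len(positive)
    while i < n:
        theta = positive[i][0]
        while i < n and positive[i][0] == theta:
            a, b = positive[i][1]
            uf.union(a, b)
            i += 1
        if seeds_connected():
            return theta
    raise SeedsNotConnectable(
        f"seeds {seeds} span disconnected positive-relevance components"
    )


@dataclass
class ExpandedSubnetwork:
    """One pathway's expansion in one phenotype network."""

    pathway_id: str
    phenotype: str | None
    seed_set: frozenset[str]
    theta: float
    kept_edges: frozenset[tuple[str, str]]
    node_set: frozenset[str] = field(init=False)
    expanded_genes: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        endpoints = {g for e in self.kept_edges for g in e}
        # isolated seeds remain members of the subnetwork by definition
        self.node_set = frozenset(self.seed_set | endpoints)
        self.expanded_genes = frozenset(self.node_set - self.seed_set)


def extract_subnetwork(
    relevance: EdgeRelevanceMap,
    seed_set: frozenset[str] | set[str],
    theta: float,
    pathway_id: str = "",
    phenotype: str | None = None,
) -> ExpandedSubnetwork:
    """Keep every edge with ER >= theta; nodes are seeds plus endpoints."""
    kept = frozenset(e for e, er in relevance.relevance.items() if er >= theta and er > 0.0)
    return ExpandedSubnetwork(
        pathway_id=pathway_id,
        phenotype=phenotype,
        seed_set=frozenset(seed_set),
        theta=float(theta),
        kept_edges=kept,
    )


@dataclass
class UnionSubnetwork:
    """Edge-set union of one pathway's two phenotype expansions."""

    pathway_id: str
    union_nodes: frozenset[str]
    union_edges: frozenset[tuple[str, str]]


def union_subnetworks(
    sub_a: ExpandedSubnetwork, sub_b: ExpandedSubnetwork
) -> UnionSubnetwork:
    if sub_a.pathway_id != sub_b.pathway_id:
        raise ValueError(
            f"cannot union different pathways: {sub_a.pathway_id!r} vs {sub_b.pathway_id!r}"
        )
    return UnionSubnetwork(
        pathway_id=sub_a.pathway_id,
        union_nodes=frozenset(sub_a.node_set | sub_b.node_set),
        union_edges=frozenset(sub_a.kept_edges | sub_b.kept_edges),
    )


def expand_pathway(
    network: WeightedNetwork,
    pathway_genes,
    pathway_id: str = "",
    l_max: int = DEFAULT_L_MAX,
    mode: str = "weighted",
    start_weights: dict[str, float] | None = None,
) -> tuple[ExpandedSubnetwork | None, str | None, EdgeRelevanceMap | None]:
    """Run the full single-network expansion for one pathway.

    Returns ``(subnetwork, skip_reason, relevance_map)``; exactly one of
    ``subnetwork`` / ``skip_reason`` is set.
    """
    seeds, skip = map_seed(pathway_genes, network)
    if skip is not None:
        return None, skip, None
    try:
        rel = edge_relevance(
            network, seeds, l_max=l_max, start_weights=start_weights, mode=mode
        )
    except NegligibleAbsorption:
        return None, SKIP_UNCONNECTABLE, None
    try:
        theta = select_threshold(rel, rel.effective_seeds)
    except SeedsNotConnectable:
        return None, SKIP_UNCONNECTABLE, rel
    sub = extract_subnetwork(
        rel, seeds, theta, pathway_id=pathway_id, phenotype=network.phenotype
    )
    return sub, None, rel


def expansion_report(
    gene_sets: GeneSetCollection,
    subnetworks: dict[str, dict[str, ExpandedSubnetwork]],
    network: WeightedNetwork | None = None,
) -> pd.DataFrame:
    """Original-vs-expanded gene counts, one row per pathway.

    ``subnetworks`` maps pathway_id -> phenotype -> ExpandedSubnetwork;
    pathways absent from the mapping (skipped) get n_expanded 0 and a
    "skipped" status. Passing ``network`` lets mapped-gene counts be
    reported for skipped pathways too.
    """
    rows = []
    for pathway_id, name, genes in gene_sets:
        subs = subnetworks.get(pathway_id, {})
        if subs:
            any_sub = next(iter(subs.values()))
            n_mapped = len(any_sub.seed_set)
            union_nodes = frozenset().union(*(s.node_set for s in subs.values()))
            n_expanded = len(union_nodes)
            status = "expanded"
        else:
            n_mapped = (
                len(map_seed(genes, network)[0]) if network is not None else 0
            )
            n_expanded = 0
            status = "skipped"
        rows.append(
            {
                "pathway_id": pathway_id,
                "name": name,
                "n_original_genes": len(genes),
                "n_mapped_genes": n_mapped,
                "n_expanded_genes_total": n_expanded,
                "status": status,
            }
        )
    return pd.DataFrame(rows)
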