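"""Pathway scoring by cross-phenotype decorrelation of subnetwork weights.

Every pathway's union subnetwork is mapped back into the two phenotype
networks to give two edge-weight vectors over one canonical edge ordering;
the pathway score is

    Score = 1 - |Corr(T_w, N_w)|

where Corr is the Pearson correlation of the two vectors. A score near 1
means the pathway neighborhood's co-expression pattern is rewired between
the phenotypes; near 0 means the pattern is preserved. The score is a
ranking statistic, not a p-value — no multiple-testing correction applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expansion import (
    ExpandedSubnetwork,
    UnionSubnetwork,
    expand_pathway,
    union_subnetworks,
)
from .io_formats import ExpressionDataset, GeneSetCollection, PpiEdgeList
from .kwalk import DEFAULT_L_MAX
from .network import WeightedNetwork, build_phenotype_pair

logger = logging.getLogger(__name__)

STATUS_SCORED = "scored"
STATUS_LT2 = "skipped_lt2_seed"
STATUS_UNCONNECTABLE = "skipped_unconnectable"
STATUS_DEGENERATE = "skipped_degenerate_vectors"


class DegenerateVectors(ValueError):
    """Weight vectors too short or constant; correlation undefined."""


@dataclass
class PathwayScoreRecord:
    pathway_id: str
    name: str
    status: str
    score: float | None = None
    abs_corr: float | None = None
    n_union_edges: int = 0
    theta_A: float | None = None
    theta_B: float | None = None
    n_seed_genes: int = 0
    n_expanded_A: int = 0
    n_expanded_B: int = 0
    rank: int | None = None


@dataclass
class AnalysisConfig:
    """Tunable parameters of the end-to-end run.

    beta
        Exponent on |Pearson correlation| in the edge weights (default 1).
    l_max
        Maximal walk length of the limited k-walks expansion (default 50).
    mode
        Aggregation of per-length passage expectations: "weighted"
        (probability-weighted conditional expectation, default) or "literal"
        (plain sum over lengths).
    start_dist
        Initial distribution over walk starts; only "uniform" is built in.
    """

    beta: float = 1.0
    l_max: int = DEFAULT_L_MAX
    mode: str = "weighted"
    start_dist: str = "uniform"

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.l_max < 1:
            raise ValueError("l_max must be >= 1")
        if self.mode not in ("weighted", "literal"):
            raise ValueError("mode must be 'weighted' or 'literal'")
        if self.start_dist != "uniform":
            raise ValueError("only the uniform start distribution is supported")


@dataclass
class AnalysisResult:
    records: list[PathwayScoreRecord]
    networks: tuple[WeightedNetwork, WeightedNetwork]
    subnetworks: dict[str, dict[str, ExpandedSubnetwork]] = field(default_factory=dict)
    unions: dict[str, UnionSubnetwork] = field(default_factory=dict)

    @property
    def scored(self) -> list[PathwayScoreRecord]:
        return [r for r in self.records if r.status == STATUS_SCORED]


def edge_weight_vectors(
    union: UnionSubnetwork, net_a: WeightedNetwork, net_b: WeightedNetwork
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """The union subnetwork's weight vectors in the two phenotype networks.

    Both vectors follow one canonical ordering (lexicographic on the
    canonical edge pairs), so the result is invariant to input edge order.
    """
    edges = sorted(union.union_edges)
    if not edges:
        raise ValueError(f"union subnetwork {union.pathway_id!r} has no edges")
    wa = net_a.edge_weight_map()
    wb = net_b.edge_weight_map()
    try:
        t_w = np.array([wa[e] for e in edges], dtype=float)
        n_w = np.array([wb[e] for e in edges], dtype=float)
    except KeyError as exc:
        raise ValueError(
            f"union edge {exc.args[0]} absent from a phenotype network; "
            "the two networks must share their topology"
        ) from exc
    return t_w, n_w, edges


def pearson_corr(t_w: np.ndarray, n_w: np.ndarray) -> float:
    """Pearson correlation of two equal-length weight vectors.

    Computed from the definitional sums (centered cross product over the
    product of centered norms). Raises :class:`DegenerateVectors` for n < 2
    or a zero-variance vector.
    """
    t_w = np.asarray(t_w, dtype=float)
    n_w = np.asarray(n_w, dtype=float)
    if t_w.shape != n_w.shape or t_w.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    n = t_w.size
    if n < 2:
        raise DegenerateVectors(f"need >= 2 edges for a correlation, got {n}")
    tc = t_w - t_w.mean()
    nc = n_w - n_w.mean()
    denom = np.sqrt((tc**2).sum() * (nc**2).sum())
    if denom == 0.0:
        raise DegenerateVectors("zero variance in a weight vector")
    return float(np.clip((tc * nc).sum() / denom, -1.0, 1.0))


def score_pathway(
    union: UnionSubnetwork,
    net_a: WeightedNetwork,
    net_b: WeightedNetwork,
    name: str = "",
) -> PathwayScoreRecord:
    """Score = 1 - |Pearson corr| of the union's weight vectors."""
    record = PathwayScoreRecord(
        pathway_id=union.pathway_id,
        name=name,
        status=STATUS_SCORED,
        n_union_edges=len(union.union_edges),
    )
    try:
        t_w, n_w, _ = edge_weight_vectors(union, net_a, net_b)
        corr = pearson_corr(t_w, n_w)
    except (DegenerateVectors, ValueError) as exc:
        logger.info("pathway %s not scoreable: %s", union.pathway_id, exc)
        record.status = STATUS_DEGENERATE
        return record
    record.abs_corr = abs(corr)
    record.score = 1.0 - abs(corr)
    return record


def _rank(records: list[PathwayScoreRecord]) -> list[PathwayScoreRecord]:
    scored = [r for r in records if r.status == STATUS_SCORED]
    skipped = [r for r in records if r.status != STATUS_SCORED]
    scored.sort(key=lambda r: (-r.score, r.pathway_id))
    for i, r in enumerate(scored, start=1):
        r.rank = i
    skipped.sort(key=lambda r: r.pathway_id)
    return scored + skipped


def run_analysis(
    expr: ExpressionDataset,
    ppi: PpiEdgeList,
    gene_sets: GeneSetCollection,
    config: AnalysisConfig | None = None,
) -> AnalysisResult:
    """End-to-end run: networks, per-pathway expansion, union, score, rank.

    The returned records are ordered scored-first by descending score (ties
    broken by pathway id), then skipped pathways; each pathway's statuses
    and counts are logged.
    """
    config = config or AnalysisConfig()
    net_a, net_b = build_phenotype_pair(expr, ppi, beta=config.beta)
    pheno_a, pheno_b = expr.phenotypes

    records: list[PathwayScoreRecord] = []
    subnetworks: dict[str, dict[str, ExpandedSubnetwork]] = {}
    unions: dict[str, UnionSubnetwork] = {}
    for pathway_id, name, genes in gene_sets:
        record = PathwayScoreRecord(pathway_id=pathway_id, name=name, status=STATUS_SCORED)
        subs = {}
        skip = None
        for pheno, net in ((pheno_a, net_a), (pheno_b, net_b)):
            sub, reason, _ = expand_pathway(
                net, genes, pathway_id=pathway_id, l_max=config.l_max, mode=config.mode
            )
            if reason is not None:
                skip = reason
                break
            subs[pheno] = sub
        if skip is not None:
            record.status = skip
            seeds = frozenset(g for g in genes if g in net_a)
            record.n_seed_genes = len(seeds)
            records.append(record)
            logger.info("pathway %s: %s", pathway_id, skip)
            continue

        sub_a, sub_b = subs[pheno_a], subs[pheno_b]
        union = union_subnetworks(sub_a, sub_b)
        scored = score_pathway(union, net_a, net_b, name=name)
        scored.n_seed_genes = len(sub_a.seed_set)
        scored.theta_A = sub_a.theta
        scored.theta_B = sub_b.theta
        scored.n_expanded_A = len(sub_a.node_set)
        scored.n_expanded_B = len(sub_b.node_set)
        records.append(scored)
        subnetworks[pathway_id] = subs
        unions[pathway_id] = union
        logger.info(
            "pathway %s: status=%s score=%s union_edges=%d",
            pathway_id,
            scored.status,
            f"{scored.score:.6f}" if scored.score is not None else "NA",
            scored.n_union_edges,
        )

    records = _rank(records)
    return AnalysisResult(
        records=records, networks=(net_a, net_b), subnetworks=subnetworks, unions=unions
    )


def disease_overlap_report(
    gene_sets: GeneSetCollection,
    subnetworks: dict[str, dict[str, ExpandedSubnetwork]],
    disease_genes,
) -> pd.DataFrame:
    """Pathway / disease-gene-set overlap before and after expansion."""
    disease = frozenset(disease_genes)
    rows = []
    for pathway_id, name, genes in gene_sets:
        subs = subnetworks.get(pathway_id, {})
        if subs:
            expanded_nodes = frozenset().union(*(s.node_set for s in subs.values()))
        else:
            expanded_nodes = frozenset()
        rows.append(
            {
                "pathway_id": pathway_id,
                "name": name,
                "overlap_before": len(frozenset(genes) & disease),
                "overlap_after": len(expanded_nodes & disease),
            }
        )
    return pd.DataFrame(rows)
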