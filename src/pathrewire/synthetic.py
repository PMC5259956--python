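"""Synthetic two-phenotype studies with planted differential co-expression.

The generator emulates the kind of input the pipeline consumes in practice —
a PPI-like topology, a gene x sample expression matrix per phenotype, and a
pathway collection — with one *planted* pathway whose neighborhood
co-expression differs between the phenotypes while decoy pathways are
phenotype-invariant.

Co-expression is induced by a module-factor construction: every pathway is a
co-expression module with one latent standard-normal factor per module, and
each member gene ``i`` loads on its module's factor with ``sqrt(q_i)``. The
per-gene strengths ``q_i`` are drawn once from the topology/pathway seed
(centered on the module's target correlation, spread ``loading_spread``) and
shared between the phenotypes, so the expected correlation of an in-module
edge, ``sqrt(q_i q_j)``, is a reproducible gene-pair property. Residual
noise tops each gene's variance up to exactly 1, so in-module edge
correlations hit their targets in expectation; genes belonging to several
modules are rescaled into the unit variance budget when necessary (logged).
Edges with no shared module are uncorrelated noise.

Decoy modules use the background center in both phenotypes; the planted
module uses ``planted_corr[0]`` in the first phenotype and
``planted_corr[1]`` in the second (a center of 0 removes the module's factor
entirely in that phenotype). With the default spread, realized decoy edge
weights vary reproducibly across edges — the pattern the pathway score
measures the preservation of.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io_formats import ExpressionDataset, GeneSetCollection, PpiEdgeList

logger = logging.getLogger(__name__)

PLANTED_ID = "PW_PLANTED"
SINGLE_GENE_ID = "PW_SINGLE"

_Q_MIN, _Q_MAX = 0.02, 0.95


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic two-phenotype dataset.

    Defaults describe a desk-scale study: a 300-gene preferential-attachment
    topology of ~900 edges, 100 samples per phenotype, decoy modules
    centered at correlation 0.5 in both phenotypes, and one planted module
    centered at 0.8 in phenotype A but absent (0.0) in phenotype B.
    """

    n_genes: int = 300
    n_edges: int = 900
    n_samples: int = 100  # per phenotype
    n_decoy_pathways: int = 20
    pathway_size: tuple[int, int] = (10, 20)
    background_corr: float = 0.5
    planted_corr: tuple[float, float] = (0.8, 0.0)
    loading_spread: float = 0.35
    noise_sd: float = 0.2  # residual-noise floor per gene
    topology: str = "preferential_attachment"  # or "random"
    phenotypes: tuple[str, str] = ("tumor", "normal")
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.background_corr, *self.planted_corr):
            if not (0 <= r < 1):
                raise ValueError(f"target correlation {r} must satisfy 0 <= r < 1")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples per phenotype")
        if self.n_genes < 3:
            raise ValueError("need at least 3 genes")
        lo, hi = self.pathway_size
        if lo < 2 or hi < lo:
            raise ValueError("pathway_size must be (lo, hi) with 2 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError("pathway size exceeds n_genes")
        if not 0 <= self.loading_spread < 1:
            raise ValueError("loading_spread must lie in [0, 1)")
        if self.topology not in ("preferential_attachment", "random"):
            raise ValueError("topology must be 'preferential_attachment' or 'random'")


@dataclass
class ModuleSpec:
    """One co-expression module: member genes and per-phenotype centers."""

    genes: tuple[str, ...]
    centers: tuple[float, float]


@dataclass
class SimulatedStudy:
    expression: ExpressionDataset
    ppi: PpiEdgeList
    gene_sets: GeneSetCollection
    planted_id: str
    planted_genes: frozenset[str]
    config: SimulationConfig = field(repr=False, default=None)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_topology(config: SimulationConfig, seed: int | None = None) -> PpiEdgeList:
    """Connected undirected topology over ``n_genes`` named genes.

    ``preferential_attachment`` grows a Barabasi-Albert graph with the
    attachment count chosen to approximate ``n_edges`` (heavy-tailed degrees,
    as in real PPI networks); ``random`` draws a G(n, m) graph and patches
    connectivity by linking components. Deterministic given the seed.
    """
    rng_seed = config.seed if seed is None else seed
    n = config.n_genes
    if config.topology == "preferential_attachment":
        m = max(1, round(config.n_edges / n))
        if m >= n:
            raise ValueError(f"n_edges {config.n_edges} infeasible for {n} genes")
        g = nx.barabasi_albert_graph(n, m, seed=rng_seed)
    else:
        max_edges = n * (n - 1) // 2
        if config.n_edges > max_edges or config.n_edges < n - 1:
            raise ValueError(
                f"n_edges {config.n_edges} infeasible for a connected graph on {n} genes"
            )
        g = nx.gnm_random_graph(n, config.n_edges, seed=rng_seed)
        rng = np.random.default_rng(rng_seed)
        comps = [sorted(c) for c in nx.connected_components(g)]
        while len(comps) > 1:
            # splice each extra component into the first with one random edge
            a = int(rng.choice(comps[0]))
            b = int(rng.choice(comps[1]))
            g.add_edge(a, b)
            comps = [sorted(c) for c in nx.connected_components(g)]
    mapping = {i: _gene_name(i) for i in g.nodes}
    pairs = [(mapping[a], mapping[b]) for a, b in g.edges]
    return PpiEdgeList.from_pairs(pairs)


def _connected_subset(
    graph: nx.Graph,
    size: int,
    rng: np.random.Generator,
    forbidden: frozenset[str] = frozenset(),
) -> frozenset[str]:
    """Random connected node subset grown by randomized BFS.

    Nodes in ``forbidden`` are never included (used to keep decoy pathways
    disjoint from the planted genes, so decoy correlation targets really are
    phenotype-invariant).
    """
    candidates = sorted(set(graph.nodes) - forbidden)
    if not candidates:
        raise ValueError("no admissible start node")
    for _ in range(100):
        start = candidates[rng.integers(len(candidates))]
        chosen = {start}
        frontier = sorted(set(graph.neighbors(start)) - forbidden)
        while len(chosen) < size and frontier:
            nxt = frontier[rng.integers(len(frontier))]
            chosen.add(nxt)
            frontier = sorted(
                {nb for c in chosen for nb in graph.neighbors(c)} - chosen - forbidden
            )
        if len(chosen) == size:
            return frozenset(chosen)
    raise ValueError(f"could not grow a connected subset of size {size}")


def plant_pathways(
    topology: PpiEdgeList, config: SimulationConfig, seed: int | None = None
) -> tuple[GeneSetCollection, frozenset[str]]:
    """Planted + decoy pathway collection, plus the planted gene set.

    Every pathway is a random connected subset of the topology so that
    in-module edges exist. A deliberate single-gene pathway is appended to
    exercise the |S| >= 2 skip rule.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    graph = nx.Graph(sorted(topology.edges))
    lo, hi = config.pathway_size
    entries = []
    planted_size = int(rng.integers(lo, hi + 1))
    planted = _connected_subset(graph, planted_size, rng)
    entries.append((PLANTED_ID, "planted differentially wired pathway", tuple(sorted(planted))))
    for k in range(config.n_decoy_pathways):
        size = int(rng.integers(lo, hi + 1))
        decoy = _connected_subset(graph, size, rng, forbidden=planted)
        entries.append((f"PW_DECOY_{k:03d}", f"decoy pathway {k}", tuple(sorted(decoy))))
    lone = rng.choice(sorted(graph.nodes))
    entries.append((SINGLE_GENE_ID, "single-gene skip probe", (str(lone),)))
    return GeneSetCollection(entries=entries), planted


def modules_from_gene_sets(
    gene_sets: GeneSetCollection, planted_id: str, config: SimulationConfig
) -> list[ModuleSpec]:
    """Translate a pathway collection into co-expression module specs.

    Decoy pathways become modules centered at ``background_corr`` in both
    phenotypes; the planted pathway uses ``planted_corr``; single-gene
    entries induce no co-expression and are dropped.
    """
    modules = []
    r_bg = config.background_corr
    for set_id, _, genes in gene_sets:
        if len(genes) < 2:
            continue
        centers = config.planted_corr if set_id == planted_id else (r_bg, r_bg)
        modules.append(ModuleSpec(genes=tuple(genes), centers=centers))
    return modules


def _loading_offsets(
    modules: list[ModuleSpec], config: SimulationConfig, structure_seed: int
) -> list[np.ndarray]:
    """Per-gene loading offsets u_{i,m}, drawn once and shared by phenotypes."""
    rng = np.random.default_rng(structure_seed)
    return [
        rng.uniform(-config.loading_spread, config.loading_spread, size=len(m.genes))
        for m in modules
    ]


def _phenotype_loadings(
    modules: list[ModuleSpec],
    offsets: list[np.ndarray],
    phenotype_idx: int,
    genes: list[str],
) -> np.ndarray:
    """Loading-strength matrix q (gene x module) for one phenotype."""
    gidx = {g: i for i, g in enumerate(genes)}
    q = np.zeros((len(genes), len(modules)))
    for m, (spec, u) in enumerate(zip(modules, offsets)):
        center = spec.centers[phenotype_idx]
        if center == 0.0:
            continue  # module absent in this phenotype
        vals = np.clip(center + u, _Q_MIN, _Q_MAX)
        for g, qv in zip(spec.genes, vals):
            if g in gidx:
                q[gidx[g], m] = qv
    return q


def expected_edge_targets(
    topology: PpiEdgeList,
    config: SimulationConfig,
    modules: list[ModuleSpec],
    phenotype: str,
    structure_seed: int,
) -> dict[tuple[str, str], float]:
    """Expected per-edge correlations implied by the module construction.

    For an edge (i, j) the target is ``sum_m sqrt(q_im q_jm)`` over shared
    modules, after the same unit-variance rescaling applied when sampling.
    """
    genes = sorted(topology.genes)
    pidx = config.phenotypes.index(phenotype)
    offsets = _loading_offsets(modules, config, structure_seed)
    q = _phenotype_loadings(modules, offsets, pidx, genes)
    q = _rescale_into_budget(q, config.noise_sd)
    L = np.sqrt(q)
    gidx = {g: i for i, g in enumerate(genes)}
    return {
        e: float(L[gidx[e[0]]] @ L[gidx[e[1]]]) for e in topology.edges
    }


def _rescale_into_budget(q: np.ndarray, noise_sd: float) -> np.ndarray:
    """Shrink multi-module loadings into the unit variance budget."""
    budget = 1.0 - noise_sd**2
    total = q.sum(axis=1)
    over = total > budget
    if over.any():
        logger.info(
            "%d genes exceed the unit variance budget; module loadings rescaled",
            int(over.sum()),
        )
        q = q.copy()
        q[over] *= (budget / total[over])[:, None]
    return q


def simulate_expression(
    topology: PpiEdgeList,
    config: SimulationConfig,
    phenotype: str,
    modules: list[ModuleSpec],
    structure_seed: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """One phenotype's gene x sample matrix under the module-factor model.

    Rows follow the sorted gene order of the topology. ``structure_seed``
    fixes the per-gene loading strengths (shared across phenotypes);
    ``seed`` drives the factor and noise draws (distinct per phenotype).
    Every gene has unit variance; in-module edge correlations equal their
    targets in expectation (see :func:`expected_edge_targets`).
    """
    if phenotype not in config.phenotypes:
        raise KeyError(f"unknown phenotype {phenotype!r}")
    pidx = config.phenotypes.index(phenotype)
    if structure_seed is None:
        structure_seed = config.seed + 1000
    if seed is None:
        seed = config.seed + 10 + pidx
    genes = sorted(topology.genes)
    offsets = _loading_offsets(modules, config, structure_seed)
    q = _phenotype_loadings(modules, offsets, pidx, genes)
    q = _rescale_into_budget(q, config.noise_sd)
    L = np.sqrt(q)

    rng = np.random.default_rng(seed)
    n_g, n_s = len(genes), config.n_samples
    F = rng.standard_normal((len(modules), n_s)) if modules else np.zeros((0, n_s))
    resid_sd = np.sqrt(1.0 - q.sum(axis=1))
    return L @ F + resid_sd[:, None] * rng.standard_normal((n_g, n_s))


def generate_study(config: SimulationConfig) -> SimulatedStudy:
    """Full reproducible study: topology, pathways, two-phenotype expression."""
    root = np.random.SeedSequence(config.seed)
    s_topo, s_path, s_struct, s_a, s_b = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(5)
    )
    topology = generate_topology(config, seed=s_topo)
    gene_sets, planted = plant_pathways(topology, config, seed=s_path)
    modules = modules_from_gene_sets(gene_sets, PLANTED_ID, config)
    genes = tuple(sorted(topology.genes))
    pheno_a, pheno_b = config.phenotypes
    xa = simulate_expression(topology, config, pheno_a, modules, s_struct, seed=s_a)
    xb = simulate_expression(topology, config, pheno_b, modules, s_struct, seed=s_b)
    samples_a = tuple(f"{pheno_a[:1].upper()}{i:03d}" for i in range(config.n_samples))
    samples_b = tuple(f"{pheno_b[:1].upper()}{i:03d}" for i in range(config.n_samples))
    labels = {**{s: pheno_a for s in samples_a}, **{s: pheno_b for s in samples_b}}
    expr = ExpressionDataset(
        genes=genes,
        samples=samples_a + samples_b,
        values=np.hstack([xa, xb]),
        labels=labels,
    )
    return SimulatedStudy(
        expression=expr,
        ppi=topology,
        gene_sets=gene_sets,
        planted_id=PLANTED_ID,
        planted_genes=planted,
        config=config,
    )


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the study in the same formats the readers consume.

    Emits expression.tsv, labels.tsv, ppi.tsv, pathways.gmt and truth.tsv
    (planted annotation) under ``out_dir``; returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "ppi": out / "ppi.tsv",
        "gmt": out / "pathways.gmt",
        "truth": out / "truth.tsv",
    }
    expr = study.expression
    with open(paths["expression"], "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(expr.samples) + "\n")
        for g, row in zip(expr.genes, expr.values):
            fh.write(g + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    with open(paths["labels"], "w", encoding="utf-8") as fh:
        fh.write("sample_id\tphenotype\n")
        for s in expr.samples:
            fh.write(f"{s}\t{expr.labels[s]}\n")
    with open(paths["ppi"], "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(study.ppi.edges):
            fh.write(f"{a}\t{b}\n")
    with open(paths["gmt"], "w", encoding="utf-8") as fh:
        for set_id, desc, genes in study.gene_sets:
            fh.write("\t".join((set_id, desc, *genes)) + "\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("pathway_id\trole\tgenes\n")
        for set_id, _, genes in study.gene_sets:
            role = "planted" if set_id == study.planted_id else (
                "single_gene_probe" if set_id == SINGLE_GENE_ID else "decoy"
            )
            fh.write(f"{set_id}\t{role}\t{','.join(genes)}\n")
    return paths
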