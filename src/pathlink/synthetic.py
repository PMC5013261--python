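"""Synthetic universes, expression datasets, and association tables.

Everything here is a pure function of its seed, so pipeline stages can be
tested end to end with known planted structure and no external downloads.
Generated artifacts use exactly the TSV formats the readers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import ExpressionDataset, MeasureType
from .linkage import AssociationTable
from .pathway_model import PathwayGraph, PathwayUniverse


@dataclass(frozen=True)
class UniverseParams:
    """Shape of a synthetic pathway universe."""

    n_pathways: int = 50
    min_genes: int = 4
    max_genes: int = 8
    edge_density: float = 0.3  # extra edges beyond the spanning tree, per possible edge
    n_too_small: int = 0
    n_flagged: int = 0
    genes_per_node: int = 1

    def __post_init__(self) -> None:
        if self.min_genes < 1 or self.max_genes < self.min_genes:
            raise ValueError("need 1 <= min_genes <= max_genes")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must be in [0, 1]")
        if self.n_pathways < 0 or self.n_too_small < 0 or self.n_flagged < 0:
            raise ValueError("counts must be nonnegative")
        if self.genes_per_node < 1:
            raise ValueError("genes_per_node must be >= 1")


@dataclass(frozen=True)
class SyntheticScenario:
    """A full planted-signal scenario: universe, exposure, diseases, truth."""

    seed: int = 0
    universe_params: UniverseParams = field(default_factory=UniverseParams)
    exposure_pathways: tuple[str, ...] = ()
    effect_size: float = 0.2
    measure_type: MeasureType = MeasureType.ONE_MINUS_P
    n_background_genes: int = 2000
    disease_plants: dict[str, tuple[str, ...]] = field(default_factory=dict)
    background_association_rate: float = 0.02
    plant_association_prob: float = 0.8


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """Shipped reference scenario: exposure and a matched disease planted on
    the same 5 pathways of a 50-pathway universe, plus a disjoint control."""
    planted = tuple(f"P{i:03d}" for i in range(1, 6))
    control = tuple(f"P{i:03d}" for i in range(6, 11))
    return SyntheticScenario(
        seed=seed,
        universe_params=UniverseParams(n_pathways=50),
        exposure_pathways=planted,
        effect_size=0.2,
        measure_type=MeasureType.ONE_MINUS_P,
        n_background_genes=2000,
        disease_plants={"matched": planted, "control": control},
    )


def _random_connected_graph(
    n_nodes: int, density: float, rng: np.random.Generator
) -> set[frozenset[int]]:
    """Uniform random spanning tree plus extra edges at the given density."""
    edges: set[frozenset[int]] = set()
    if n_nodes <= 1:
        return edges
    # random tree: attach each node to a uniformly chosen earlier node of a
    # random permutation (uniform over labeled trees is not needed here)
    order = rng.permutation(n_nodes)
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        edges.add(frozenset((int(order[i]), int(order[j]))))
    for u in range(n_nodes):
        for v in range(u + 1, n_nodes):
            e = frozenset((u, v))
            if e not in edges and rng.random() < density:
                edges.add(e)
    return edges


def make_universe(
    params: UniverseParams, seed: int
) -> tuple[PathwayUniverse, pd.DataFrame]:
    """Generate an unfiltered universe plus a per-pathway catalog.

    Clean pathways P001.. carry ``min_genes..max_genes`` genes on connected
    random graphs; ``n_too_small`` pathways (S...) get <= 3 genes and
    ``n_flagged`` pathways (F...) alternate disease/catch-all flags.  Gene
    identifiers are globally unique across pathways ("g000001", ...).
    """
    rng = np.random.default_rng(seed)
    pathways: list[PathwayGraph] = []
    catalog_rows = []
    gene_counter = 0

    def next_genes(count: int) -> list[str]:
        nonlocal gene_counter
        out = [f"g{gene_counter + i + 1:06d}" for i in range(count)]
        gene_counter += count
        return out

    def build(pid: str, n_genes: int, disease: bool, catchall: bool) -> PathwayGraph:
        gpn = params.genes_per_node
        n_nodes = max(1, -(-n_genes // gpn))  # ceil
        genes = next_genes(n_genes)
        node_ids = [f"{pid}.n{i + 1}" for i in range(n_nodes)]
        node_genes = {nid: set() for nid in node_ids}
        for i, g in enumerate(genes):
            node_genes[node_ids[i % n_nodes]].add(g)
        raw_edges = _random_connected_graph(n_nodes, params.edge_density, rng)
        edges = {frozenset((node_ids[u], node_ids[v])) for u, v in raw_edges}
        return PathwayGraph(
            pathway_id=pid, name=f"synthetic pathway {pid}",
            nodes=set(node_ids), edges=edges, node_genes=node_genes,
            is_disease_pathway=disease, is_catchall=catchall,
        )

    for i in range(params.n_pathways):
        n_genes = int(rng.integers(params.min_genes, params.max_genes + 1))
        pid = f"P{i + 1:03d}"
        pathways.append(build(pid, n_genes, False, False))
        catalog_rows.append((pid, "clean", n_genes))
    for i in range(params.n_too_small):
        n_genes = int(rng.integers(1, 4))  # 1..3 genes: always filtered
        pid = f"S{i + 1:03d}"
        pathways.append(build(pid, n_genes, False, False))
        catalog_rows.append((pid, "too_small", n_genes))
    for i in range(params.n_flagged):
        n_genes = int(rng.integers(params.min_genes, params.max_genes + 1))
        pid = f"F{i + 1:03d}"
        disease = i % 2 == 0
        pathways.append(build(pid, n_genes, disease, not disease))
        catalog_rows.append((pid, "disease_flag" if disease else "catchall_flag",
                             n_genes))

    catalog = pd.DataFrame(catalog_rows, columns=["pathway_id", "kind", "n_genes"])
    return PathwayUniverse(pathways=pathways), catalog


def simulate_dataset(
    universe: PathwayUniverse,
    planted_ids: tuple[str, ...] | list[str],
    delta: float,
    measure_type: MeasureType,
    n_background_genes: int,
    seed: int,
    code: str = "synthetic",
) -> ExpressionDataset:
    """One value per gene (universe genes plus a background pool).

    Null model: ONE_MINUS_P ~ U(0,1); LOG2_RATIO ~ N(0,1); INDICATOR ~
    Bernoulli(0.05).  Genes of the planted pathways shift by delta:
    ONE_MINUS_P ~ U(1-delta, 1); LOG2_RATIO ~ +-(|N(0,1)| + 3*delta) with a
    random sign; INDICATOR ~ Bernoulli(min(1, 0.05 + delta)).
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must be in [0, 1]")
    measure_type = MeasureType(measure_type)
    rng = np.random.default_rng(seed)
    known = {p.pathway_id for p in universe.pathways}
    stray = set(planted_ids) - known
    if stray:
        raise ValueError(f"planted pathway ids not in universe: {sorted(stray)}")

    planted_genes: set[str] = set()
    for p in universe.pathways:
        if p.pathway_id in planted_ids:
            planted_genes |= p.genes
    background = universe.genes - planted_genes
    background |= {f"bg{i + 1:06d}" for i in range(n_background_genes)}

    values: dict[str, float] = {}
    for gene in sorted(background):
        values[gene] = _draw(rng, measure_type, 0.0)
    for gene in sorted(planted_genes):
        values[gene] = _draw(rng, measure_type, delta)
    return ExpressionDataset(
        code=code, measure_type=measure_type, values=values,
        provenance=f"synthetic, delta={delta}, seed={seed}",
    )


def _draw(rng: np.random.Generator, measure_type: MeasureType, delta: float) -> float:
    if measure_type is MeasureType.ONE_MINUS_P:
        return float(rng.uniform(1.0 - delta, 1.0)) if delta > 0 else float(rng.uniform())
    if measure_type is MeasureType.LOG2_RATIO:
        base = float(rng.standard_normal())
        if delta <= 0:
            return base
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return sign * (abs(base) + 3.0 * delta)
    rate = min(1.0, 0.05 + delta)
    return float(rng.random() < rate)


def simulate_associations(
    universe: PathwayUniverse,
    disease_plants: dict[str, tuple[str, ...]],
    background_rate: float,
    seed: int,
    plant_prob: float = 0.8,
) -> AssociationTable:
    """Associate each disease's planted-pathway genes with prob ``plant_prob``
    and every other universe gene with prob ``background_rate``."""
    if not 0.0 <= background_rate <= 1.0 or not 0.0 <= plant_prob <= 1.0:
        raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    known = {p.pathway_id: p for p in universe.pathways}
    all_genes = sorted(universe.genes)
    records: list[tuple[str, str]] = []
    for disease in sorted(disease_plants):
        planted: set[str] = set()
        for pid in disease_plants[disease]:
            if pid not in known:
                raise ValueError(f"disease {disease!r} plants unknown pathway {pid!r}")
            planted |= known[pid].genes
        for gene in all_genes:
            prob = plant_prob if gene in planted else background_rate
            if prob > 0 and rng.random() < prob:
                records.append((gene, disease))
    return AssociationTable(records=records)


def scenario_truth(scenario: SyntheticScenario) -> pd.DataFrame:
    """Intended exposure-disease overlaps: one row per planted disease."""
    exposure = set(scenario.exposure_pathways)
    rows = []
    for disease in sorted(scenario.disease_plants):
        planted = set(scenario.disease_plants[disease])
        shared = exposure & planted
        rows.append((disease, len(shared), ";".join(sorted(shared))))
    return pd.DataFrame(rows, columns=["disease_class", "expected_overlap",
                                       "shared_pathway_ids"])


# ---------------------------------------------------------------------------
# TSV emission in the exact formats the readers consume


def write_universe_tables(universe: PathwayUniverse, out_dir) -> dict[str, str]:
    """Write nodes/edges/flags TSVs for ``read_pathway_tables``."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    node_rows, edge_rows, flag_rows = [], [], []
    for p in universe.pathways:
        for node in sorted(p.nodes):
            genes = sorted(p.node_genes.get(node, set()))
            if genes:
                node_rows.extend((p.pathway_id, node, g) for g in genes)
            else:
                node_rows.append((p.pathway_id, node, ""))
        for e in sorted(tuple(sorted(edge)) for edge in p.edges):
            edge_rows.append((p.pathway_id, e[0], e[1]))
        flag_rows.append(
            (p.pathway_id, int(p.is_disease_pathway), int(p.is_catchall))
        )
    paths = {
        "nodes": str(out / "pathway_nodes.tsv"),
        "edges": str(out / "pathway_edges.tsv"),
        "flags": str(out / "pathway_flags.tsv"),
    }
    pd.DataFrame(node_rows, columns=["pathway_id", "node_id", "gene_id"]).to_csv(
        paths["nodes"], sep="\t", index=False)
    pd.DataFrame(edge_rows, columns=["pathway_id", "node_u", "node_v"]).to_csv(
        paths["edges"], sep="\t", index=False)
    pd.DataFrame(flag_rows,
                 columns=["pathway_id", "is_disease_pathway", "is_catchall"]).to_csv(
        paths["flags"], sep="\t", index=False)
    return paths


def write_associations(table: AssociationTable, path) -> None:
    pd.DataFrame(table.records, columns=["gene_id", "disease_class"]).to_csv(
        path, sep="\t", index=False)
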