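"""Pathway graphs: KGML and TSV readers, universe filtering, node distances.

A pathway is an undirected, gene-labeled graph.  Nodes correspond to KGML
entries (genes, orthologs, or groups of either); each node carries a set of
canonical gene identifiers (Entrez-style, stored as strings).  The universe
filter removes pathways that are too small, flagged as disease pathways, or
flagged as catch-alls, and records a per-pathway log of the decision.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Filter-exclusion reasons.
TOO_FEW_GENES = "too_few_genes"
DISEASE_PATHWAY = "disease_pathway"
CATCHALL = "catchall"
RETAINED = "retained"

#: KGML entry types that become graph nodes.
_NODE_ENTRY_TYPES = frozenset({"gene", "ortholog", "group"})

#: Default minimum gene count: pathways with 3 or fewer genes are excluded.
DEFAULT_MIN_GENES = 4


class KgmlParseError(ValueError):
    """Raised for malformed KGML input; message carries the byte offset."""


class PathwayTableError(ValueError):
    """Raised for inconsistent node/edge/flag tables."""


@dataclass
class PathwayGraph:
    """One pathway as a gene-labeled undirected graph."""

    pathway_id: str
    name: str = ""
    nodes: set[str] = field(default_factory=set)
    edges: set[frozenset[str]] = field(default_factory=set)
    node_genes: dict[str, set[str]] = field(default_factory=dict)
    is_disease_pathway: bool = False
    is_catchall: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for edge in self.edges:
            for endpoint in edge:
                if endpoint not in self.nodes:
                    raise ValueError(
                        f"pathway {self.pathway_id!r}: edge endpoint {endpoint!r} "
                        "is not a node"
                    )
        extra = set(self.node_genes) - self.nodes
        if extra:
            raise ValueError(
                f"pathway {self.pathway_id!r}: node_genes keys {sorted(extra)} "
                "are not nodes"
            )

    @property
    def genes(self) -> set[str]:
        """Union of all gene identifiers on the pathway's nodes."""
        out: set[str] = set()
        for gs in self.node_genes.values():
            out |= gs
        return out

    def gene_count(self) -> int:
        return len(self.genes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g


@dataclass
class PathwayUniverse:
    """An ordered collection of pathways plus the filter bookkeeping.

    ``M`` is the retained-pathway count; ``filter_log`` maps pathway_id to a
    reason string (``retained`` or one of the exclusion reasons).  An
    unfiltered universe has every pathway retained and an empty log.
    """

    pathways: list[PathwayGraph] = field(default_factory=list)
    filter_log: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.pathways:
            if p.pathway_id in seen:
                raise ValueError(f"duplicate pathway id {p.pathway_id!r}")
            seen.add(p.pathway_id)

    @property
    def M(self) -> int:
        return len(self.pathways)

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]

    @property
    def genes(self) -> set[str]:
        """Union of genes over retained pathways."""
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return out

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def filter_log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(pid, reason) for pid, reason in self.filter_log.items()],
            columns=["pathway_id", "status"],
        )


@dataclass
class DistanceTable:
    """All-pairs shortest-path lengths (edge steps) for one pathway.

    Unreachable pairs are simply absent from ``dist``; :meth:`get` returns
    ``None`` for them.
    """

    pathway_id: str
    dist: dict[tuple[str, str], int]

    def get(self, u: str, v: str) -> int | None:
        if u == v:
            return 0
        key = (u, v) if u <= v else (v, u)
        return self.dist.get(key)

    def reachable(self, u: str, v: str) -> bool:
        return self.get(u, v) is not None


def _parse_gene_tokens(name_attr: str) -> set[str]:
    """Parse a KGML ``name`` attribute like ``"hsa:5923 hsa:5924"``.

    Tokens are split on whitespace; an organism prefix up to ``:`` is
    stripped.  Tokens that are not integer identifiers (e.g. ``undefined``)
    are ignored.
    """
    genes: set[str] = set()
    for token in name_attr.split():
        ident = token.split(":", 1)[-1]
        if ident.isdigit():
            genes.add(ident)
    return genes


def read_kgml(source) -> PathwayGraph:
    """Read one KGML document into a :class:`PathwayGraph`.

    ``source`` is a path or open file.  Entries of type gene/ortholog/group
    become nodes keyed by their KGML entry id; each relation between two
    retained entries becomes one undirected edge.  Group entries carry the
    union of their component entries' genes.  Relations naming an unknown or
    non-retained entry are skipped with a warning.
    """
    try:
        tree = ET.parse(source)
    except ET.ParseError as err:
        line, col = err.position
        offset = _byte_offset(source, line, col)
        raise KgmlParseError(
            f"malformed KGML at byte offset {offset} (line {line}, column {col}): {err}"
        ) from err
    root = tree.getroot()
    pathway_id = root.get("name", "").split(":", 1)[-1] or "unknown"
    title = root.get("title", "")

    nodes: set[str] = set()
    node_genes: dict[str, set[str]] = {}
    entry_genes: dict[str, set[str]] = {}
    components: dict[str, list[str]] = {}
    for entry in root.iter("entry"):
        eid = entry.get("id")
        etype = entry.get("type", "")
        if eid is None:
            continue
        entry_genes[eid] = _parse_gene_tokens(entry.get("name", ""))
        if etype not in _NODE_ENTRY_TYPES:
            continue
        nodes.add(eid)
        node_genes[eid] = set(entry_genes[eid])
        if etype == "group":
            components[eid] = [
                c.get("id") for c in entry.iter("component") if c.get("id")
            ]

    # groups get the union of member genes
    for gid, member_ids in components.items():
        for mid in member_ids:
            node_genes[gid] |= entry_genes.get(mid, set())

    edges: set[frozenset[str]] = set()
    for relation in root.iter("relation"):
        e1, e2 = relation.get("entry1"), relation.get("entry2")
        if e1 not in nodes or e2 not in nodes:
            logger.warning(
                "pathway %s: relation (%s, %s) references an unknown node; skipped",
                pathway_id, e1, e2,
            )
            continue
        if e1 != e2:
            edges.add(frozenset((e1, e2)))

    return PathwayGraph(
        pathway_id=pathway_id, name=title,
        nodes=nodes, edges=edges, node_genes=node_genes,
    )


def _byte_offset(source, line: int, col: int) -> int:
    """Best-effort byte offset of (line, col) in the source document."""
    try:
        if hasattr(source, "read"):
            source.seek(0)
            raw = source.read()
            data = raw.encode() if isinstance(raw, str) else raw
        else:
            with open(source, "rb") as fh:
                data = fh.read()
    except OSError:
        return -1
    lines = data.split(b"\n")
    return sum(len(ln) + 1 for ln in lines[: line - 1]) + col


def read_kgml_dir(directory) -> PathwayUniverse:
    """Read every ``*.xml``/``*.kgml`` file under ``directory`` (sorted)."""
    import pathlib

    paths = sorted(
        p for p in pathlib.Path(directory).iterdir()
        if p.suffix.lower() in {".xml", ".kgml"}
    )
    return PathwayUniverse(pathways=[read_kgml(p) for p in paths])


def read_pathway_tables(nodes_file, edges_file, flags_file=None) -> PathwayUniverse:
    """Build an unfiltered universe from plain TSV tables.

    nodes: (pathway_id, node_id, gene_id) — blank gene_id makes a gene-less
    node; edges: (pathway_id, node_u, node_v); flags (optional):
    (pathway_id, is_disease_pathway, is_catchall) with 0/1 values.
    Duplicate rows deduplicate under set semantics.  An edge naming a node
    or pathway absent from the nodes file is a hard error listing the rows.
    """
    nodes_df = pd.read_csv(nodes_file, sep="\t", dtype=str, keep_default_na=False)
    edges_df = pd.read_csv(edges_file, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(nodes_df, ["pathway_id", "node_id", "gene_id"], "nodes")
    _require_columns(edges_df, ["pathway_id", "node_u", "node_v"], "edges")

    nodes: dict[str, set[str]] = {}
    node_genes: dict[str, dict[str, set[str]]] = {}
    for row in nodes_df.itertuples(index=False):
        nodes.setdefault(row.pathway_id, set()).add(row.node_id)
        genes = node_genes.setdefault(row.pathway_id, {}).setdefault(row.node_id, set())
        if row.gene_id:
            genes.add(row.gene_id)

    edges: dict[str, set[frozenset[str]]] = {pid: set() for pid in nodes}
    bad_rows = []
    for i, row in enumerate(edges_df.itertuples(index=False)):
        pid = row.pathway_id
        if pid not in nodes or row.node_u not in nodes[pid] or row.node_v not in nodes[pid]:
            bad_rows.append(i + 2)  # 1-based, after header
            continue
        if row.node_u != row.node_v:
            edges[pid].add(frozenset((row.node_u, row.node_v)))
    if bad_rows:
        raise PathwayTableError(
            f"edges file references unknown pathways or nodes at rows {bad_rows}"
        )

    flags: dict[str, tuple[bool, bool]] = {}
    if flags_file is not None:
        flags_df = pd.read_csv(flags_file, sep="\t", dtype=str, keep_default_na=False)
        _require_columns(
            flags_df, ["pathway_id", "is_disease_pathway", "is_catchall"], "flags"
        )
        for row in flags_df.itertuples(index=False):
            flags[row.pathway_id] = (
                _parse_bool(row.is_disease_pathway),
                _parse_bool(row.is_catchall),
            )

    pathways = []
    for pid in nodes:  # insertion order == file order of first appearance
        disease, catchall = flags.get(pid, (False, False))
        pathways.append(
            PathwayGraph(
                pathway_id=pid,
                nodes=nodes[pid],
                edges=edges[pid],
                node_genes=node_genes[pid],
                is_disease_pathway=disease,
                is_catchall=catchall,
            )
        )
    return PathwayUniverse(pathways=pathways)


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in {"1", "true", "yes"}


def _require_columns(df: pd.DataFrame, cols: list[str], label: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise PathwayTableError(f"{label} file is missing columns {missing}")


def filter_universe(
    universe: PathwayUniverse, min_genes: int = DEFAULT_MIN_GENES
) -> PathwayUniverse:
    """Apply the universe filter: drop small, disease, and catch-all pathways.

    A pathway is retained iff its gene count is >= ``min_genes`` and both
    flags are false.  Each excluded pathway carries exactly one reason, with
    ``too_few_genes`` checked first.  Idempotent.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    retained: list[PathwayGraph] = []
    log: dict[str, str] = {}
    for p in universe.pathways:
        if p.gene_count() < min_genes:
            log[p.pathway_id] = TOO_FEW_GENES
        elif p.is_disease_pathway:
            log[p.pathway_id] = DISEASE_PATHWAY
        elif p.is_catchall:
            log[p.pathway_id] = CATCHALL
        else:
            log[p.pathway_id] = RETAINED
            retained.append(p)
    if not retained:
        logger.warning("universe filter retained no pathways")
    return PathwayUniverse(pathways=retained, filter_log=log)


def node_distances(graph: PathwayGraph) -> DistanceTable:
    """All-pairs shortest-path lengths on the undirected pathway graph."""
    g = graph.to_networkx()
    dist: dict[tuple[str, str], int] = {}
    for u, lengths in nx.all_pairs_shortest_path_length(g):
        for v, d in lengths.items():
            if u < v:
                dist[(u, v)] = d
    return DistanceTable(pathway_id=graph.pathway_id, dist=dist)
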