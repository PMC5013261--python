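import textwrap

import pytest

from pathlink.pathway_model import PathwayGraph, PathwayUniverse


KGML_TWO_GENES = textwrap.dedent("""\
    <?xml version="1.0"?>
    <pathway name="path:hsa00010" org="hsa" number="00010" title="Two gene demo">
      <entry id="1" name="hsa:10" type="gene"/>
      <entry id="2" name="hsa:20" type="gene"/>
      <relation entry1="1" entry2="2" type="PPrel">
        <subtype name="activation" value="--&gt;"/>
      </relation>
    </pathway>
    """)

KGML_BAD_RELATION = textwrap.dedent("""\
    <?xml version="1.0"?>
    <pathway name="path:hsa00020" org="hsa" number="00020" title="Dangling relation">
      <entry id="1" name="hsa:10" type="gene"/>
      <entry id="2" name="hsa:20" type="gene"/>
      <relation entry1="1" entry2="99" type="PPrel"/>
    </pathway>
    """)

KGML_GROUP = textwrap.dedent("""\
    <?xml version="1.0"?>
    <pathway name="path:hsa00030" org="hsa" number="00030" title="Group demo">
      <entry id="1" name="hsa:10" type="gene"/>
      <entry id="2" name="hsa:20 hsa:30" type="gene"/>
      <entry id="3" name="undefined" type="group">
        <component id="1"/>
        <component id="2"/>
      </entry>
    </pathway>
    """)


@pytest.fixture
def kgml_file(tmp_path):
    def write(content, name="pathway.xml"):
        path = tmp_path / name
        path.write_text(content, encoding="utf-8")
        return path

    return write


def make_pathway(pid, genes, edges=(), chain=True, **flags):
    """A pathway with one gene per node; nodes chained unless edges given."""
    nodes = [f"{pid}.n{i + 1}" for i in range(len(genes))]
    node_genes = {n: {g} for n, g in zip(nodes, genes)}
    if edges:
        edge_set = {frozenset(e) for e in edges}
    elif chain and len(nodes) > 1:
        edge_set = {frozenset((a, b)) for a, b in zip(nodes, nodes[1:])}
    else:
        edge_set = set()
    return PathwayGraph(pathway_id=pid, nodes=set(nodes), edges=edge_set,
                        node_genes=node_genes, **flags)


@pytest.fixture
def ten_pathway_universe():
    """2 too-small, 1 disease-flagged, 1 catchall, 6 clean."""
    pathways = [
        make_pathway("small1", ["a1", "a2"]),
        make_pathway("small2", ["b1", "b2", "b3"]),
        make_pathway("dis1", ["c1", "c2", "c3", "c4"], is_disease_pathway=True),
        make_pathway("catch1", ["d1", "d2", "d3", "d4"], is_catchall=True),
    ] + [
        make_pathway(f"clean{i}", [f"e{i}{j}" for j in range(5)])
        for i in range(6)
    ]
    return PathwayUniverse(pathways=pathways)


@pytest.fixture
def write_tsv(tmp_path):
    def write(name, header, rows):
        path = tmp_path / name
        lines = ["\t".join(header)] + ["\t".join(str(c) for c in r) for r in rows]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return write
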