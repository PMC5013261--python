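# pathlink

Topology-aware pathway enrichment and exposure–disease linkage for
transcriptomics data.

`pathlink` implements a three-step procedure for predicting linkages between
an exposure and classes of human disease from per-gene expression measures:

1. **Disease → pathway**: gene–disease association tables are converted to
   0/1 indicator datasets and enriched against a pathway universe; pathways
   with p < 0.01 form each disease's significant set (size N).
2. **Exposure → pathway**: per-gene expression measures (log₂ ratios,
   1 − p significance measures, or 0/1 indicators) are enriched against the
   same universe; pathways with p < 0.05 form each dataset's set (size K).
3. **Exposure → disease**: the overlap X between the two sets, inside a
   filtered universe of M pathways, is scored with the exact upper-tail
   hypergeometric probability 1 − H(X−1, M, K, N).

Enrichment uses a topology-weighted rank statistic: per-gene magnitudes are
converted to normalized average-tie ranks, projected onto pathway nodes
(max over a node's measured genes), and combined as

    S = Σᵤ ρᵤ + Σ_{u<v, d(u,v)≤D} λ^{d(u,v)−1} ρᵤ ρᵥ

with shortest-path distances d on the undirected pathway graph. Significance
comes from a seeded permutation null (ranks redrawn from the measured-gene
universe without replacement, add-one p-value estimator). A structure-blind
`mean_rank` statistic is available behind the same interface.

## Layout

| module | contents |
| --- | --- |
| `pathlink.pathway_model` | pathway graphs, KGML and TSV readers, universe filter (≥4 genes, no disease/catch-all flags), node distances |
| `pathlink.expression_io` | measure conventions, score/id-map readers, probe→gene collapsing, replicate and pooled datasets |
| `pathlink.enrichment` | rank transform, topology-weighted statistic, permutation p-values |
| `pathlink.linkage` | association tables, disease/exposure pathway sets, exact hypergeometric CDF and upper tail |
| `pathlink.synthetic` | seeded generators for universes, datasets, and association tables with planted signal |
| `pathlink.pipeline` / `pathlink.cli` | end-to-end orchestration, report bundle, `pathlink` CLI |

## CLI

```sh
# generate a fully synthetic scenario (planted exposure + diseases)
pathlink simulate --seed 1 --out-dir sim/

# run the full pipeline from those files
pathlink pipeline \
    --pathways sim/pathway_nodes.tsv --edges sim/pathway_edges.tsv \
    --flags sim/pathway_flags.tsv \
    --scores SYN=sim/scores_SYN.tsv:ONE_MINUS_P \
    --assoc sim/associations.tsv \
    --permutations 999 --seed 1 --out-dir out/
```

Subcommands `enrich`, `disease-map`, and `link` run the individual stages;
`pathlink pipeline --synthetic --out-dir out/` regenerates the default
scenario inline, and `--config FILE` reads a flat key=value file mirroring
the flags. The output bundle contains the universe filter log, per-dataset
enrichment TSVs, the disease-set table, a styled linkage matrix (4-decimal
p-values, "-" for zero-overlap cells, trailing "# Linked pathways" column),
a machine-readable linkage table, the shared-pathway footnote file, and a
JSON manifest echoing the effective configuration.

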