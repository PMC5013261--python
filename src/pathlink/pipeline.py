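"""End-to-end pipeline: filter universe, enrich datasets, map diseases,
link exposures to diseases, and write a Table-style report bundle.

The bundle written to ``out_dir``:

* ``filter_log.tsv``        — per-pathway retained/excluded + reason
* ``enrichment_<CODE>.tsv`` — per-dataset enrichment results
* ``disease_sets.tsv``      — disease class, gene count, pathway count
* ``linkage_matrix.tsv``    — datasets x disease classes, 4-decimal p-values,
  zero-overlap cells rendered "-", trailing "# Linked pathways" column (K)
* ``linkage_long.tsv``      — machine-readable grid with numeric p for every cell
* ``shared_pathways.tsv``   — footnote analog: shared ids per significant cell
* ``manifest.json``         — seed, versions, effective configuration
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import sys
import time
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .enrichment import EnrichmentConfig, enrich_all, write_results
from .expression_io import MeasureType, map_ids, read_idmap, read_scores
from .linkage import (
    ALPHA_DISEASE,
    ALPHA_EXPOSURE,
    LinkageResult,
    disease_pathway_sets,
    exposure_pathway_sets,
    link_exposure_disease,
    read_associations,
)
from .pathway_model import filter_universe, read_kgml_dir, read_pathway_tables

logger = logging.getLogger(__name__)

M_POLICIES = ("universe", "evaluable")

_CONFIG_KEYS = {
    "pathway_nodes", "pathway_edges", "pathway_flags", "kgml_dir",
    "scores", "assoc", "idmap", "out_dir",
    "alpha_disease", "alpha_exposure",
    "lambda_decay", "max_distance", "permutations", "seed", "statistic",
    "min_genes", "universe_m_policy", "synthetic", "synthetic_seed",
}


@dataclass
class RunConfig:
    """Resolved pipeline configuration; echoed verbatim into the manifest."""

    out_dir: str
    pathway_nodes: str | None = None
    pathway_edges: str | None = None
    pathway_flags: str | None = None
    kgml_dir: str | None = None
    scores: list[tuple[str, str, str]] = field(default_factory=list)  # (code, path, measure)
    assoc: str | None = None
    idmap: str | None = None
    alpha_disease: float = ALPHA_DISEASE
    alpha_exposure: float = ALPHA_EXPOSURE
    min_genes: int = 4
    universe_m_policy: str = "universe"
    synthetic: bool = False
    synthetic_seed: int = 0
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    def __post_init__(self) -> None:
        if self.universe_m_policy not in M_POLICIES:
            raise ValueError(f"unknown M policy {self.universe_m_policy!r}")


def read_config_file(path) -> RunConfig:
    """Parse a flat key=value config file mirroring the CLI flags.

    ``scores`` entries take the repeatable form ``CODE=FILE:MEASURE`` joined
    by commas.  Unknown keys are rejected.
    """
    raw: dict[str, str] = {}
    for lineno, line in enumerate(
        pathlib.Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        key = key.strip()
        if key not in _CONFIG_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        raw[key] = value.strip()

    enrichment = EnrichmentConfig(
        lambda_decay=float(raw.get("lambda_decay", 0.5)),
        max_distance=int(raw.get("max_distance", 3)),
        permutations=int(raw.get("permutations", 10_000)),
        seed=int(raw.get("seed", 0)),
        statistic_name=raw.get("statistic", "topology_weighted"),
    )
    scores = [parse_scores_spec(s) for s in raw.get("scores", "").split(",") if s]
    return RunConfig(
        out_dir=raw.get("out_dir", "pathlink_out"),
        pathway_nodes=raw.get("pathway_nodes"),
        pathway_edges=raw.get("pathway_edges"),
        pathway_flags=raw.get("pathway_flags"),
        kgml_dir=raw.get("kgml_dir"),
        scores=scores,
        assoc=raw.get("assoc"),
        idmap=raw.get("idmap"),
        alpha_disease=float(raw.get("alpha_disease", ALPHA_DISEASE)),
        alpha_exposure=float(raw.get("alpha_exposure", ALPHA_EXPOSURE)),
        min_genes=int(raw.get("min_genes", 4)),
        universe_m_policy=raw.get("universe_m_policy", "universe"),
        synthetic=raw.get("synthetic", "false").lower() in {"1", "true", "yes"},
        synthetic_seed=int(raw.get("synthetic_seed", raw.get("seed", 0))),
        enrichment=enrichment,
    )


def parse_scores_spec(spec: str) -> tuple[str, str, str]:
    """Parse one ``CODE=FILE:MEASURE`` scores flag."""
    try:
        code, rest = spec.split("=", 1)
        path, measure = rest.rsplit(":", 1)
        MeasureType(measure)
    except ValueError as err:
        raise ValueError(
            f"bad scores spec {spec!r}; expected CODE=FILE:MEASURE with MEASURE "
            f"one of {[m.value for m in MeasureType]}"
        ) from err
    return code, path, measure


class StageError(RuntimeError):
    """A pipeline stage failure, named by stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as err:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, err) from err
            logger.info("stage %-12s %6.2fs", name, time.perf_counter() - t0)
            return result
        return wrapped
    return deco


@_stage("universe")
def _load_universe(config: RunConfig, out: pathlib.Path):
    from . import synthetic

    if config.synthetic:
        scenario = synthetic.default_scenario(seed=config.synthetic_seed)
        universe, _ = synthetic.make_universe(
            scenario.universe_params, scenario.seed
        )
        inputs = out / "inputs"
        synthetic.write_universe_tables(universe, inputs)
    elif config.kgml_dir:
        universe = read_kgml_dir(config.kgml_dir)
    elif config.pathway_nodes and config.pathway_edges:
        universe = read_pathway_tables(
            config.pathway_nodes, config.pathway_edges, config.pathway_flags
        )
    else:
        raise ValueError("no pathway source configured")
    filtered = filter_universe(universe, min_genes=config.min_genes)
    filtered.filter_log_frame().to_csv(out / "filter_log.tsv", sep="\t", index=False)
    return filtered


@_stage("datasets")
def _load_datasets(config: RunConfig, universe, out: pathlib.Path):
    from . import synthetic
    from .expression_io import write_scores

    if config.synthetic:
        scenario = synthetic.default_scenario(seed=config.synthetic_seed)
        ds = synthetic.simulate_dataset(
            universe, scenario.exposure_pathways, scenario.effect_size,
            scenario.measure_type, scenario.n_background_genes,
            seed=scenario.seed, code="SYN",
        )
        write_scores(ds, out / "inputs" / "scores_SYN.tsv")
        return [ds]
    idmap = read_idmap(config.idmap) if config.idmap else None
    datasets = []
    for code, path, measure in config.scores:
        ds = read_scores(path, MeasureType(measure), code=code)
        if idmap is not None:
            ds, report = map_ids(ds, idmap)
            logger.info(
                "dataset %s: mapped=%d collapsed=%d dropped=%d",
                code, report.mapped, report.collapsed, report.dropped,
            )
        datasets.append(ds)
    return datasets


@_stage("associations")
def _load_associations(config: RunConfig, universe, out: pathlib.Path):
    from . import synthetic

    if config.synthetic:
        scenario = synthetic.default_scenario(seed=config.synthetic_seed)
        table = synthetic.simulate_associations(
            universe, scenario.disease_plants,
            scenario.background_association_rate, seed=scenario.seed,
            plant_prob=scenario.plant_association_prob,
        )
        synthetic.write_associations(table, out / "inputs" / "associations.tsv")
        return table
    if not config.assoc:
        raise ValueError("no association table configured")
    return read_associations(config.assoc)


def run_pipeline(config: RunConfig) -> dict:
    """Run all three steps and write the report bundle; returns the manifest."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    universe = _load_universe(config, out)
    datasets = _load_datasets(config, universe, out)
    associations = _load_associations(config, universe, out)

    exposure_sets = []
    evaluable_m: dict[str, int] = {}
    for ds in datasets:
        try:
            results = enrich_all(universe, ds, config.enrichment)
        except Exception as err:  # noqa: BLE001
            raise StageError("enrichment", err) from err
        write_results(results, out / f"enrichment_{ds.code}.tsv")
        exposure_sets.append(
            exposure_pathway_sets(results, owner=ds.code,
                                  alpha=config.alpha_exposure)
        )
        evaluable_m[ds.code] = sum(1 for r in results if r.evaluable)

    try:
        disease_sets = disease_pathway_sets(
            associations, universe, config.enrichment, alpha=config.alpha_disease
        )
    except Exception as err:  # noqa: BLE001
        raise StageError("disease-map", err) from err
    pd.DataFrame(
        [(d.owner, d.n_genes, d.size) for d in disease_sets],
        columns=["disease_class", "n_genes", "n_pathways"],
    ).to_csv(out / "disease_sets.tsv", sep="\t", index=False)

    try:
        linkage_results = []
        for e in exposure_sets:
            m = universe.M if config.universe_m_policy == "universe" \
                else evaluable_m[e.owner]
            for d in disease_sets:
                linkage_results.append(link_exposure_disease(e, d, m))
    except Exception as err:  # noqa: BLE001
        raise StageError("linkage", err) from err

    k_by_dataset = {e.owner: e.size for e in exposure_sets}
    write_linkage_table(linkage_results, out / "linkage_matrix.tsv",
                        k_by_dataset=k_by_dataset)
    write_linkage_long(linkage_results, out / "linkage_long.tsv")
    write_shared_pathways(linkage_results, out / "shared_pathways.tsv",
                          alpha=config.alpha_exposure)

    manifest = {
        "tool": "pathlink",
        "version": __version__,
        "python": sys.version.split()[0],
        "config": _config_dict(config),
        "M": universe.M,
        "n_datasets": len(datasets),
        "n_disease_classes": len(disease_sets),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["scores"] = [list(s) for s in config.scores]
    return d


def write_linkage_table(
    results: list[LinkageResult], path, k_by_dataset: dict[str, int] | None = None
) -> pd.DataFrame:
    """Write the styled linkage matrix: datasets x disease classes.

    Cells are p-values to 4 decimal places; zero-overlap cells render as
    "-"; a trailing "# Linked pathways" column carries K per dataset.
    """
    datasets, diseases = [], []
    for r in results:
        if r.dataset_code not in datasets:
            datasets.append(r.dataset_code)
        if r.disease_class not in diseases:
            diseases.append(r.disease_class)
    cell = {(r.dataset_code, r.disease_class): r for r in results}
    if k_by_dataset is None:
        k_by_dataset = {r.dataset_code: r.K for r in results}
    rows = []
    for code in datasets:
        row: dict[str, object] = {"dataset": code}
        for disease in diseases:
            r = cell.get((code, disease))
            row[disease] = "-" if r is None or r.X == 0 else f"{r.p_value:.4f}"
        row["# Linked pathways"] = k_by_dataset.get(code, 0)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_linkage_long(results: list[LinkageResult], path) -> pd.DataFrame:
    """Machine-readable linkage grid; numeric p (1.0 for X = 0) in every row."""
    df = pd.DataFrame(
        [
            (r.dataset_code, r.disease_class, r.X, r.M, r.K, r.N, r.p_value,
             ";".join(sorted(r.shared_pathway_ids)))
            for r in results
        ],
        columns=["dataset", "disease_class", "X", "M", "K", "N", "p_value",
                 "shared_pathway_ids"],
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def write_shared_pathways(
    results: list[LinkageResult], path, alpha: float = ALPHA_EXPOSURE
) -> pd.DataFrame:
    """Footnote analog: shared pathway ids for each significant cell."""
    df = pd.DataFrame(
        [
            (r.dataset_code, r.disease_class, r.p_value,
             ";".join(sorted(r.shared_pathway_ids)))
            for r in results
            if r.X > 0 and r.p_value < alpha
        ],
        columns=["dataset", "disease_class", "p_value", "shared_pathway_ids"],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
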