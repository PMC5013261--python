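"""Per-gene expression measures: readers, identifier mapping, pooling.

Three measure conventions are supported for the single per-gene value fed
to enrichment:

* ``LOG2_RATIO`` — log2 exposed/control ratio, any finite real;
* ``ONE_MINUS_P`` — one minus a per-gene significance p-value, in [0, 1];
* ``INDICATOR`` — 0/1 flag for a significantly altered gene.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)


class MeasureType(enum.Enum):
    LOG2_RATIO = "LOG2_RATIO"
    ONE_MINUS_P = "ONE_MINUS_P"
    INDICATOR = "INDICATOR"


@dataclass
class ExpressionDataset:
    """Per-gene measures under one declared convention."""

    code: str
    measure_type: MeasureType
    values: dict[str, float]
    field_type: str = "synthetic"  # RF | LF | ELF | synthetic
    provenance: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.measure_type, str):
            self.measure_type = MeasureType(self.measure_type)
        for gene, value in self.values.items():
            _check_range(gene, value, self.measure_type)

    @property
    def genes(self) -> set[str]:
        return set(self.values)

    def __len__(self) -> int:
        return len(self.values)


def _check_range(gene: str, value: float, measure_type: MeasureType) -> None:
    if not math.isfinite(value):
        raise ValueError(f"gene {gene!r}: non-finite value {value!r}")
    if measure_type is MeasureType.ONE_MINUS_P and not 0.0 <= value <= 1.0:
        raise ValueError(
            f"gene {gene!r}: ONE_MINUS_P value {value!r} outside [0, 1]"
        )
    if measure_type is MeasureType.INDICATOR and value not in (0.0, 1.0):
        raise ValueError(f"gene {gene!r}: INDICATOR value {value!r} not in {{0, 1}}")


@dataclass
class IdMap:
    """Source identifier (probe, symbol, accession) -> canonical gene ids.

    Many-to-one and one-to-many entries are both permitted, so each source
    maps to a *set* of canonical ids.
    """

    mapping: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, targets in self.mapping.items():
            if not src or not all(targets):
                raise ValueError(f"blank key or value in id map entry {src!r}")

    @classmethod
    def from_pairs(cls, pairs) -> "IdMap":
        mapping: dict[str, set[str]] = {}
        for src, dst in pairs:
            mapping.setdefault(src, set()).add(dst)
        return cls(mapping=mapping)


@dataclass
class MappingReport:
    mapped: int = 0
    collapsed: int = 0
    dropped: int = 0


def read_scores(
    path, measure_type: MeasureType, code: str = "", field_type: str = "synthetic"
) -> ExpressionDataset:
    """Read a TSV of (gene_id, value) under a declared measure convention.

    Out-of-range values and duplicate gene ids are hard errors naming the
    offending row (1-based, counting the header as row 1).
    """
    measure_type = MeasureType(measure_type)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: expected columns (gene_id, value)")
    values: dict[str, float] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        gene = str(row.gene_id)
        value = float(row.value)
        if gene in values:
            raise ValueError(f"{path}: duplicate gene id {gene!r} at row {i + 2}")
        try:
            _check_range(gene, value, measure_type)
        except ValueError as err:
            raise ValueError(f"{path}: row {i + 2}: {err}") from err
        values[gene] = value
    return ExpressionDataset(
        code=code or str(path), measure_type=measure_type,
        values=values, field_type=field_type, provenance=f"read from {path}",
    )


def read_idmap(path) -> IdMap:
    """Read a TSV id map with columns (source_id, canonical_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "source_id" not in df.columns or "canonical_id" not in df.columns:
        raise ValueError(f"{path}: expected columns (source_id, canonical_id)")
    return IdMap.from_pairs(
        (row.source_id, row.canonical_id) for row in df.itertuples(index=False)
    )


def read_gene_list(path) -> set[str]:
    """Read a gene-list file, one identifier per line; blanks ignored."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def replicate_mean(datasets: list[ExpressionDataset]) -> ExpressionDataset:
    """Per-gene arithmetic mean over LOG2_RATIO replicates.

    Gene universes may differ; a gene's mean is over the replicates in which
    it appears, and partial coverage is logged.
    """
    if not datasets:
        raise ValueError("replicate_mean requires at least one dataset")
    if any(d.measure_type is not MeasureType.LOG2_RATIO for d in datasets):
        raise ValueError("replicate_mean requires LOG2_RATIO datasets only")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for d in datasets:
        for gene, value in d.values.items():
            sums[gene] = sums.get(gene, 0.0) + value
            counts[gene] = counts.get(gene, 0) + 1
    partial = sum(1 for c in counts.values() if c < len(datasets))
    if partial:
        logger.warning(
            "replicate_mean: %d of %d genes are missing from some replicates",
            partial, len(counts),
        )
    return ExpressionDataset(
        code="+".join(d.code for d in datasets),
        measure_type=MeasureType.LOG2_RATIO,
        values={g: sums[g] / counts[g] for g in sums},
        field_type=datasets[0].field_type,
        provenance=f"mean of {len(datasets)} replicates",
    )


def map_ids(
    dataset: ExpressionDataset, idmap: IdMap
) -> tuple[ExpressionDataset, MappingReport]:
    """Re-key a dataset from source identifiers to canonical gene ids.

    When several sources collapse onto one canonical id, the value with the
    largest magnitude is kept.  Sources with no map entry are dropped.
    """
    from .enrichment import _magnitude_of  # deferred: enrichment imports this module

    report = MappingReport()
    best: dict[str, float] = {}
    best_mag: dict[str, float] = {}
    for src, value in dataset.values.items():
        targets = idmap.mapping.get(src)
        if not targets:
            report.dropped += 1
            continue
        report.mapped += 1
        mag = _magnitude_of(value, dataset.measure_type)
        for canonical in targets:
            if canonical in best:
                report.collapsed += 1
                if mag > best_mag[canonical]:
                    best[canonical] = value
                    best_mag[canonical] = mag
            else:
                best[canonical] = value
                best_mag[canonical] = mag
    mapped = ExpressionDataset(
        code=dataset.code, measure_type=dataset.measure_type, values=best,
        field_type=dataset.field_type,
        provenance=dataset.provenance + " | ids mapped",
    )
    return mapped, report


def pool_indicator(
    gene_lists: list[set[str]], background: set[str], code: str = "pooled"
) -> ExpressionDataset:
    """Pool significant-gene lists into one 0/1 indicator dataset.

    The indicator is 1 on the union of the lists and 0 on every other
    background gene.  Significant genes missing from the background are
    added to it with a warning.
    """
    union: set[str] = set()
    for gl in gene_lists:
        union |= set(gl)
    missing = union - background
    if missing:
        logger.warning(
            "pool_indicator: %d significant genes absent from background; added",
            len(missing),
        )
    universe = background | union
    return ExpressionDataset(
        code=code, measure_type=MeasureType.INDICATOR,
        values={g: 1.0 if g in union else 0.0 for g in universe},
        provenance=f"pooled indicator over {len(gene_lists)} gene lists",
    )


def pool_measured(
    datasets: list[ExpressionDataset], code: str = "pooled"
) -> ExpressionDataset:
    """Pool heterogeneous measured datasets by mean normalized rank.

    Each dataset is rank-transformed on its own magnitude scale; a gene's
    pooled value is the mean of its normalized ranks over the datasets that
    measured it.  The result is declared ONE_MINUS_P (values in (0, 1]),
    which is scale-free and hence invariant to monotone transforms of the
    inputs.
    """
    from .enrichment import magnitude, rank_transform

    if not datasets:
        raise ValueError("pool_measured requires at least one dataset")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for d in datasets:
        rho = rank_transform(magnitude(d))
        for gene, r in rho.items():
            sums[gene] = sums.get(gene, 0.0) + r
            counts[gene] = counts.get(gene, 0) + 1
    return ExpressionDataset(
        code=code, measure_type=MeasureType.ONE_MINUS_P,
        values={g: sums[g] / counts[g] for g in sums},
        provenance=f"mean normalized rank over {len(datasets)} datasets",
    )


def write_scores(dataset: ExpressionDataset, path) -> None:
    """Write a dataset back to the (gene_id, value) TSV format."""
    df = pd.DataFrame(
        sorted(dataset.values.items()), columns=["gene_id", "value"]
    )
    df.to_csv(path, sep="\t", index=False)
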