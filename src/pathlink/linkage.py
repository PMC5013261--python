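"""Exposure-disease linkage via hypergeometric overlap of pathway sets.

The three-step procedure ends here: disease classes and exposure datasets
each yield a set of significant pathways inside one filtered universe of
size M; the chance of observing at least X pathways in common between a
K-set and an N-set is the upper hypergeometric tail 1 - H(X-1, M, K, N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .enrichment import EnrichmentConfig, EnrichmentResult, enrich_all
from .expression_io import ExpressionDataset, MeasureType
from .pathway_model import PathwayUniverse

logger = logging.getLogger(__name__)

ALPHA_DISEASE = 0.01
ALPHA_EXPOSURE = 0.05


@dataclass
class AssociationTable:
    """Gene-disease association records restricted to an include list.

    ``records`` holds (canonical gene id, disease class) pairs; classes
    outside ``include_list`` (when given) are dropped with a logged count.
    """

    records: list[tuple[str, str]]
    include_list: list[str] | None = None

    def __post_init__(self) -> None:
        if self.include_list is not None:
            keep = set(self.include_list)
            dropped = sum(1 for _, cls in self.records if cls not in keep)
            if dropped:
                logger.info(
                    "association table: %d records outside the include list ignored",
                    dropped,
                )
            self.records = [(g, c) for g, c in self.records if c in keep]

    @property
    def classes(self) -> list[str]:
        if self.include_list is not None:
            return list(self.include_list)
        seen: dict[str, None] = {}
        for _, cls in self.records:
            seen.setdefault(cls, None)
        return list(seen)

    def genes_for(self, disease_class: str) -> set[str]:
        return {g for g, c in self.records if c == disease_class}


def read_associations(path, include_list=None) -> AssociationTable:
    """Read a TSV of (gene_id, disease_class) records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene_id" not in df.columns or "disease_class" not in df.columns:
        raise ValueError(f"{path}: expected columns (gene_id, disease_class)")
    records = [(row.gene_id, row.disease_class) for row in df.itertuples(index=False)]
    return AssociationTable(records=records, include_list=include_list)


@dataclass
class PathwaySet:
    """The significant pathways for one disease class or one exposure dataset."""

    owner: str
    kind: str  # "disease" | "exposure"
    pathway_ids: set[str]
    alpha: float
    n_genes: int = 0  # mapped genes behind a disease set, 0 for exposure

    def __post_init__(self) -> None:
        if self.kind not in ("disease", "exposure"):
            raise ValueError(f"unknown pathway-set kind {self.kind!r}")

    @property
    def size(self) -> int:
        return len(self.pathway_ids)


@dataclass
class LinkageResult:
    dataset_code: str
    disease_class: str
    X: int
    M: int
    K: int
    N: int
    p_value: float
    shared_pathway_ids: set[str] = field(default_factory=set)


def _log_pmf(i: np.ndarray, M: int, K: int, N: int) -> np.ndarray:
    """log P(X = i) for X ~ Hypergeometric(M, K, N), in log-gamma space."""
    i = np.asarray(i, dtype=float)
    return (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(M - K + 1) - gammaln(N - i + 1) - gammaln(M - K - N + i + 1)
        - (gammaln(M + 1) - gammaln(N + 1) - gammaln(M - N + 1))
    )


def _check_domain(M: int, K: int, N: int) -> None:
    if M < 0 or K < 0 or N < 0:
        raise ValueError("M, K, N must be nonnegative")
    if K > M or N > M:
        raise ValueError(f"K={K} and N={N} must not exceed M={M}")


def hypergeom_cdf(x: int, M: int, K: int, N: int) -> float:
    """Exact hypergeometric CDF H(x; M, K, N), symmetric in K and N.

    The count of successes when drawing N items without replacement from M
    objects of which K are marked.  Computed as a log-gamma sum over the
    support, accurate to ~1e-12 relative error.
    """
    _check_domain(M, K, N)
    lo = max(0, K + N - M)
    hi = min(K, N)
    if x < lo:
        return 0.0
    if x >= hi:
        return 1.0
    support = np.arange(lo, x + 1)
    return float(min(1.0, np.exp(logsumexp(_log_pmf(support, M, K, N)))))


def link_probability(X: int, M: int, K: int, N: int) -> float:
    """Upper tail P(overlap >= X) = 1 - H(X-1, M, K, N).

    Computed as a direct tail sum in log space so that extreme tails (e.g.
    identical sets) keep full relative precision.  X = 0 gives 1.0.
    """
    _check_domain(M, K, N)
    hi = min(K, N)
    if X > hi:
        raise ValueError(f"X={X} exceeds min(K, N)={hi}")
    lo = max(0, K + N - M)
    if X <= lo:
        return 1.0
    support = np.arange(X, hi + 1)
    return float(min(1.0, np.exp(logsumexp(_log_pmf(support, M, K, N)))))


def disease_pathway_sets(
    associations: AssociationTable,
    universe: PathwayUniverse,
    config: EnrichmentConfig,
    alpha: float = ALPHA_DISEASE,
) -> list[PathwaySet]:
    """Enrich each disease class's 0/1 association indicator over the universe.

    The indicator is 1 for a disease-associated gene and 0 for every other
    gene appearing in the (filtered) universe; pathways with p < alpha form
    the disease's set.
    """
    universe_genes = universe.genes
    sets: list[PathwaySet] = []
    for disease in associations.classes:
        genes = associations.genes_for(disease) & universe_genes
        if not genes:
            logger.warning("disease %r: no associated genes in the universe", disease)
            sets.append(
                PathwaySet(owner=disease, kind="disease", pathway_ids=set(),
                           alpha=alpha, n_genes=0)
            )
            continue
        indicator = ExpressionDataset(
            code=f"disease:{disease}",
            measure_type=MeasureType.INDICATOR,
            values={g: 1.0 if g in genes else 0.0 for g in universe_genes},
            provenance=f"association indicator for {disease}",
        )
        results = enrich_all(universe, indicator, config)
        significant = {
            r.pathway_id for r in results if r.evaluable and r.p_value < alpha
        }
        sets.append(
            PathwaySet(owner=disease, kind="disease", pathway_ids=significant,
                       alpha=alpha, n_genes=len(genes))
        )
    return sets


def exposure_pathway_sets(
    results: list[EnrichmentResult],
    owner: str = "",
    alpha: float = ALPHA_EXPOSURE,
) -> PathwaySet:
    """Pathways significant for one exposure dataset at p < alpha (strict)."""
    significant = {r.pathway_id for r in results if r.evaluable and r.p_value < alpha}
    return PathwaySet(owner=owner, kind="exposure", pathway_ids=significant,
                      alpha=alpha)


def link_exposure_disease(
    exposure_set: PathwaySet, disease_set: PathwaySet, M: int
) -> LinkageResult:
    """Hypergeometric linkage between one exposure set and one disease set."""
    universe_check = exposure_set.size <= M and disease_set.size <= M
    if not universe_check:
        raise ValueError("a pathway set is larger than the universe M")
    shared = exposure_set.pathway_ids & disease_set.pathway_ids
    X = len(shared)
    K = exposure_set.size
    N = disease_set.size
    p = link_probability(X, M, K, N)
    return LinkageResult(
        dataset_code=exposure_set.owner, disease_class=disease_set.owner,
        X=X, M=M, K=K, N=N, p_value=p, shared_pathway_ids=shared,
    )


def link_all(
    exposure_sets: list[PathwaySet],
    disease_sets: list[PathwaySet],
    universe: PathwayUniverse,
) -> list[LinkageResult]:
    """Full dataset x disease grid of linkage results over one universe."""
    known = set(universe.pathway_ids)
    for s in (*exposure_sets, *disease_sets):
        stray = s.pathway_ids - known
        if stray:
            raise ValueError(
                f"pathway set {s.owner!r} contains ids absent from the universe: "
                f"{sorted(stray)}"
            )
    M = universe.M
    return [
        link_exposure_disease(e, d, M)
        for e in exposure_sets
        for d in disease_sets
    ]
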