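"""Background-pathway construction and per-module Fisher's exact over-representation.

Pathways are first intersected with the analysis universe (the background
PPIN gene set) and retained when the intersection has between ``min_size``
and ``max_size`` genes, inclusive.  For each (module, pathway) pair a
one-sided Fisher's exact test on the 2x2 table

    [[k, m - k], [K - k, N - K - m + k]]

gives the over-representation p-value — equivalently the hypergeometric
upper tail P(X >= k) for k overlap genes out of a module of m, a pathway of
K and a universe of N.  Benjamini-Hochberg adjustment is applied within each
module across the pathways tested, and a pathway with adjusted p < 0.05
(strict) is an ego pathway for that module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .data_io import PathwayCollection
from .errors import ValidationError
from .significance import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 5
DEFAULT_MAX_SIZE = 100
DEFAULT_ALPHA = 0.05


@dataclass
class EnrichmentResult:
    module_id: str
    pathway_id: str
    overlap: int
    module_size: int
    pathway_size: int
    universe: int
    p: float
    p_adj: float = float("nan")
    is_ego_pathway: bool = False


def build_background_pathways(
    pathways: PathwayCollection,
    universe: set[str],
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> PathwayCollection:
    """Intersect every pathway with the universe; keep sizes in [min_size, max_size]."""
    if not universe:
        raise ValidationError("pathway universe is empty")
    if min_size < 1 or max_size < min_size:
        raise ValidationError("invalid pathway size bounds")
    kept: dict[str, tuple[str, frozenset[str]]] = {}
    for name, (desc, genes) in pathways.items():
        inter = genes & universe
        if min_size <= len(inter) <= max_size:
            kept[name] = (desc, frozenset(inter))
    logger.info("background pathways: %d of %d retained", len(kept), len(pathways))
    return PathwayCollection(kept)


def fisher_enrichment(
    module_id: str,
    module_genes: set[str],
    background: PathwayCollection,
    universe: set[str],
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """One-sided Fisher's exact over-representation of a module in every background pathway."""
    module_genes = set(module_genes)
    outside = module_genes - universe
    if outside:
        raise ValidationError(f"module genes outside the universe: {sorted(outside)[:5]}")
    n = len(universe)
    m = len(module_genes)
    results: list[EnrichmentResult] = []
    for name, (_, genes) in background.items():
        k = len(module_genes & genes)
        kk = len(genes)
        table = [[k, m - k], [kk - k, n - kk - m + k]]
        _, p = stats.fisher_exact(table, alternative="greater")
        results.append(
            EnrichmentResult(
                module_id=module_id,
                pathway_id=name,
                overlap=k,
                module_size=m,
                pathway_size=kk,
                universe=n,
                p=float(p),
            )
        )
    if results:
        adj = bh_adjust([r.p for r in results])
        for r, q in zip(results, adj):
            r.p_adj = float(q)
            r.is_ego_pathway = bool(q < alpha)
    return results


def select_ego_pathways(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Filter enrichment results to the flagged ego pathways (adjusted p < alpha)."""
    return [r for r in results if r.is_ego_pathway]
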