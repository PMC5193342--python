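"""Gene-to-CNV mapping and hypergeometric gene-set enrichment.

A gene is "hit" when any CNV overlaps it by at least one basepair,
including genes that only intersect a CNV boundary.  Enrichment of a
designated gene set among the hit genes is tested by the upper tail of the
hypergeometric law: drawing ``n`` genes from a universe of ``N`` consensus
genes of which ``K`` belong to the set, the p-value is P(X >= k).  The
universe is the consensus gene file, not the genome, and duplicate hits of
one gene from multiple CNVs count once.

A removal-sensitivity sweep reports how many of the observed set genes
could be discarded before the enrichment would lose nominal significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree
from scipy import stats

from .pipeline import CnvCall, CnvRegion

__all__ = [
    "GeneModel",
    "EnrichmentResult",
    "map_regions_to_genes",
    "hypergeom_enrichment",
    "removal_sensitivity",
    "set_overlap",
]


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("gene start must be <= end")


@dataclass(frozen=True)
class EnrichmentResult:
    population_size: int  # N
    set_size: int  # K
    draws: int  # n
    hits: int  # k
    p_upper_tail: float

    @property
    def background_rate(self) -> float:
        return self.set_size / self.population_size

    @property
    def observed_rate(self) -> float:
        return self.hits / self.draws if self.draws else 0.0


def map_regions_to_genes(
    calls_or_regions: Sequence[CnvCall | CnvRegion],
    genes: Sequence[GeneModel],
) -> tuple[list[str], dict[str, list[str]]]:
    """Genes overlapped >= 1 bp by any CNV, deduplicated, plus per-sample lists.

    Returns (sorted union of hit gene symbols, {sample_id: sorted hit genes}).
    Boundary-intersecting genes count as hits.
    """
    if len({g.symbol for g in genes}) != len(genes):
        raise ValueError("gene symbols must be unique")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chromosome, IntervalTree()).addi(g.start, g.end + 1, g.symbol)
    calls: list[CnvCall] = []
    for item in calls_or_regions:
        calls.extend(item.calls if isinstance(item, CnvRegion) else [item])
    union: set[str] = set()
    per_sample: dict[str, set[str]] = {}
    for c in calls:
        tree = trees.get(c.chromosome)
        if tree is None:
            continue
        symbols = {iv.data for iv in tree.overlap(c.start, c.end + 1)}
        union |= symbols
        per_sample.setdefault(c.sample_id, set()).update(symbols)
    return sorted(union), {s: sorted(v) for s, v in per_sample.items()}


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment p-value, P(X >= k)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError("hypergeometric bounds violated")
    # survival function at k-1 gives P(X >= k); computed in log-stable form
    # by scipy's hypergeometric implementation
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(N, K, n, k, min(max(p, 0.0), 1.0))


def removal_sensitivity(N: int, K: int, n: int, k: int, alpha: float = 0.05) -> int:
    """Largest m such that removing m hits keeps enrichment below alpha.

    Only ``k`` is decremented; the draw count ``n``, set size ``K`` and
    universe ``N`` are held fixed.  Returns 0 when the observed enrichment
    is already at or above alpha.
    """
    if hypergeom_enrichment(N, K, n, k).p_upper_tail >= alpha:
        return 0
    m = 0
    while m < k and hypergeom_enrichment(N, K, n, k - (m + 1)).p_upper_tail < alpha:
        m += 1
    return m


def set_overlap(
    gene_hits: Iterable[str],
    reference_set: Iterable[str],
    universe_size: int,
) -> tuple[list[str], EnrichmentResult]:
    """Overlap of hit genes with a reference set plus its enrichment p.

    The hit genes are the draws, the reference set defines the special
    class within the consensus-gene universe of ``universe_size``.
    """
    hits = set(gene_hits)
    ref = set(reference_set)
    overlap = sorted(hits & ref)
    result = hypergeom_enrichment(universe_size, len(ref), len(hits), len(overlap))
    return overlap, result
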