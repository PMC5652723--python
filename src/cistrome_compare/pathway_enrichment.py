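"""Hypergeometric pathway enrichment of target-gene sets.

Pathways smaller than ``min_size`` genes (within the analysis universe) are
excluded. Enrichment score is observed/expected overlap; significance is a
two-sided hypergeometric test (sum of point probabilities no larger than the
observed one). Results carry a signed -log10 p for heatmap-style clustering:
positive means enriched (ES > 1), negative depleted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from cistrome_compare.formats import GeneSetCollection, ValidationError


@dataclass
class PathwayResult:
    pathway_id: str
    pathway_size: int
    overlap: int
    es: float
    p: float
    signed_log_p: float


def two_sided_hypergeom_p(k: int, N: int, K: int, n: int) -> float:
    """Two-sided hypergeometric p: sum of pmf values <= pmf(observed).

    ``k`` observed overlap, ``N`` universe size, ``K`` pathway size, ``n``
    target-set size.
    """
    support = np.arange(max(0, n + K - N), min(n, K) + 1)
    pmf = stats.hypergeom.pmf(support, N, K, n)
    observed = stats.hypergeom.pmf(k, N, K, n)
    p = float(pmf[pmf <= observed * (1 + 1e-9)].sum())
    return min(p, 1.0)


def pathway_enrichment(
    targets: set[str],
    pathways: GeneSetCollection,
    universe: set[str],
    min_size: int = 40,
) -> list[PathwayResult]:
    """Two-sided hypergeometric enrichment of one target set in each pathway.

    Pathways with fewer than ``min_size`` genes inside the universe are
    skipped (strict less-than: size exactly ``min_size`` is kept).
    """
    if not universe:
        raise ValidationError("empty gene universe")
    extra = targets - universe
    if extra:
        raise ValidationError(f"targets outside universe: {sorted(extra)[:5]}")
    N = len(universe)
    n = len(targets)
    results: list[PathwayResult] = []
    for name, genes in pathways.items():
        pw = genes & universe
        K = len(pw)
        if K < min_size:
            continue
        k = len(targets & pw)
        expected = n * K / N
        es = k / expected if expected > 0 else np.nan
        p = two_sided_hypergeom_p(k, N, K, n)
        sign = 1.0 if es > 1 else -1.0
        results.append(
            PathwayResult(name, K, k, float(es), p, float(sign * -np.log10(p)))
        )
    results.sort(key=lambda r: r.p)
    return results
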