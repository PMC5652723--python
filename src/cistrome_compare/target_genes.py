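"""Probabilistic target-gene identification from TSS-centered binding signal.

Following the TIP model, an averaged "characteristic" binding profile around
the TSS is built from all genes, each gene's signal is scored against it by
a weighted sum, scores are standardized across the cohort of genes, and an
upper-tail normal p-value with BH correction calls targets at an FDR
threshold. Per-cell-line target sets are merged into 0/1 binding-affinity
vectors, and pairwise target-set sharing is tested with the hypergeometric
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from cistrome_compare.formats import GeneRecord, SignalTrack, ValidationError
from cistrome_compare.motif_enrichment import bh_fdr

TIP_WINDOW = 10_000
TIP_BIN = 100
DEFAULT_FDR = 0.01


@dataclass
class CharacteristicProfile:
    offsets: np.ndarray  # -window..window step bin
    weights: np.ndarray  # sums to 1

    def __post_init__(self) -> None:
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValidationError("profile weights must be >= 0 and sum to 1")


def _gene_signal_matrix(
    track: SignalTrack,
    genes: list[GeneRecord],
    window: int,
    bin_width: int,
) -> tuple[np.ndarray, list[GeneRecord], int]:
    """Strand-oriented binned signal per gene; truncated-window genes skipped.

    Bin j is centered at TSS + offset_j (offsets -window..window step
    bin_width); minus-strand genes are mirrored.
    """
    offsets = np.arange(-window, window + 1, bin_width)
    half = bin_width // 2
    rows = []
    used: list[GeneRecord] = []
    skipped = 0
    cov_cache: dict[str, np.ndarray] = {}
    for g in genes:
        length = track.chrom_lengths.get(g.chrom, 0)
        if g.tss - window - half < 0 or g.tss + window + half > length:
            skipped += 1
            continue
        cov = cov_cache.get(g.chrom)
        if cov is None:
            cov = track.coverage_array(g.chrom, length)
            cov_cache[g.chrom] = cov
        offs = offsets if g.strand == "+" else -offsets
        centers = g.tss + offs
        rows.append(
            [cov[c - half:c - half + bin_width].mean() for c in centers]
        )
        used.append(g)
    if not rows:
        raise ValidationError("no gene has a complete TSS window")
    return np.asarray(rows, dtype=float), used, skipped


def characteristic_profile(
    track: SignalTrack,
    genes: list[GeneRecord],
    window: int = TIP_WINDOW,
    bin_width: int = TIP_BIN,
) -> CharacteristicProfile:
    """Average strand-oriented TSS signal over genes, normalized to sum 1."""
    X, used, _ = _gene_signal_matrix(track, genes, window, bin_width)
    if len(used) < 10:
        raise ValidationError("need >= 10 genes with full windows")
    mean = X.mean(axis=0)
    total = mean.sum()
    if total <= 0:
        raise ValidationError("aggregate TSS signal is zero; profile undefined")
    offsets = np.arange(-window, window + 1, bin_width)
    return CharacteristicProfile(offsets, mean / total)


@dataclass
class TargetGeneResult:
    gene_id: str
    raw_score: float
    z: float
    p: float
    q: float
    is_target: bool


def tip_scores(
    track: SignalTrack,
    genes: list[GeneRecord],
    profile: CharacteristicProfile,
    fdr_threshold: float = DEFAULT_FDR,
    window: int = TIP_WINDOW,
    bin_width: int = TIP_BIN,
) -> list[TargetGeneResult]:
    """Weighted TSS-signal score per gene, standardized, BH-thresholded.

    s_i = sum_j w(j) x_i(j); z_i = (s_i - mean)/sd over the gene cohort;
    p_i is the upper-tail standard-normal probability; targets have
    q < fdr_threshold.
    """
    if profile.offsets.size != (2 * window) // bin_width + 1:
        raise ValidationError("profile geometry does not match window/bin")
    X, used, _ = _gene_signal_matrix(track, genes, window, bin_width)
    s = X @ profile.weights
    sd = s.std(ddof=0)
    if sd <= 1e-12 * max(1.0, abs(s.mean())):
        raise ValidationError("all gene scores identical; z-scores undefined")
    z = (s - s.mean()) / sd
    p = stats.norm.sf(z)
    q = bh_fdr(p)
    return [
        TargetGeneResult(g.gene_id, float(si), float(zi), float(pi), float(qi),
                         bool(qi < fdr_threshold))
        for g, si, zi, pi, qi in zip(used, s, z, p, q)
    ]


def call_targets(
    track: SignalTrack,
    genes: list[GeneRecord],
    fdr_threshold: float = DEFAULT_FDR,
    window: int = TIP_WINDOW,
    bin_width: int = TIP_BIN,
) -> list[TargetGeneResult]:
    """Convenience: build the characteristic profile and score in one call."""
    profile = characteristic_profile(track, genes, window, bin_width)
    return tip_scores(track, genes, profile, fdr_threshold, window, bin_width)


def merge_cell_line_targets(
    per_experiment_targets: list[set[str]],
    universe: list[str],
) -> pd.Series:
    """0/1 binding-affinity vector over the universe: union of experiments."""
    if not per_experiment_targets:
        raise ValidationError("need at least one experiment")
    uni = set(universe)
    merged: set[str] = set()
    for t in per_experiment_targets:
        extra = set(t) - uni
        if extra:
            raise ValidationError(
                f"target genes outside the universe: {sorted(extra)[:5]}"
            )
        merged |= set(t)
    return pd.Series(
        [1 if g in merged else 0 for g in universe],
        index=pd.Index(list(universe), name="gene_id"),
        dtype=np.int8,
    )


def pairwise_target_enrichment(
    set_a: set[str], set_b: set[str], universe_size: int
) -> float:
    """Upper-tail hypergeometric p of observing >= |A intersect B| overlaps."""
    if not set_a or not set_b:
        import warnings

        warnings.warn("empty target set; enrichment p set to 1")
        return 1.0
    k = len(set_a & set_b)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(set_a), len(set_b)))


@dataclass
class TargetOverlapMatrix:
    experiments: list[str]
    neg_log10_p: pd.DataFrame
    cluster_order: list[str]


def target_overlap_matrix(
    target_sets: dict[str, set[str]], universe_size: int, cap: float = 300.0
) -> TargetOverlapMatrix:
    """-log10 hypergeometric p for every experiment pair, clustered.

    P-values below 10**-cap are capped so the distance matrix stays finite.
    """
    names = list(target_sets)
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            p = pairwise_target_enrichment(
                target_sets[names[i]], target_sets[names[j]], universe_size
            )
            v = min(-np.log10(max(p, 10.0 ** -cap)), cap)
            mat[i, j] = mat[j, i] = v
    df = pd.DataFrame(mat, index=names, columns=names)
    if n > 2:
        scale = mat.max() or 1.0
        dist = squareform(1.0 - mat / scale, checks=False)
        order = [names[i] for i in leaves_list(average(dist))]
    else:
        order = names
    return TargetOverlapMatrix(names, df, order)
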