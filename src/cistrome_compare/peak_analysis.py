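"""Peak sharing across experiments, genomic distribution, TSS meta-profiles.

A peak is "shared" between two experiments when it overlaps a peak of the
other experiment by at least 1 bp; each peak counts once regardless of how
many partners it touches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from cistrome_compare.formats import GeneRecord, Peak, SignalTrack, ValidationError
from cistrome_compare.signal_analysis import bin_signal

logger = logging.getLogger(__name__)


def _by_chrom(peaks: list[Peak]) -> dict[str, list[Peak]]:
    out: dict[str, list[Peak]] = {}
    for p in peaks:
        out.setdefault(p.interval.chrom, []).append(p)
    return out


def count_shared(peaks_a: list[Peak], peaks_b: list[Peak]) -> tuple[int, int]:
    """Number of peaks in each list overlapping (>= 1 bp) any peak of the other."""

    def one_way(queries: list[Peak], subjects: list[Peak]) -> int:
        subj = _by_chrom(subjects)
        count = 0
        prepared: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, plist in subj.items():
            starts = np.array([p.interval.start for p in plist])
            ends = np.array([p.interval.end for p in plist])
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            prepared[chrom] = (starts, np.maximum.accumulate(ends))
        for q in queries:
            got = prepared.get(q.interval.chrom)
            if got is None:
                continue
            starts, max_ends = got
            # candidates start before the query end; overlap iff one such
            # candidate extends past the query start
            idx = np.searchsorted(starts, q.interval.end, side="left")
            if idx > 0 and max_ends[idx - 1] > q.interval.start:
                count += 1
        return count

    return one_way(peaks_a, peaks_b), one_way(peaks_b, peaks_a)


@dataclass
class OverlapMatrix:
    experiments: list[str]
    shared_counts: pd.DataFrame  # counts[i, j] = peaks of i shared with j
    coefficients: pd.DataFrame  # symmetric, in [0, 1]
    cluster_order: list[str]


def overlap_matrix(experiments: dict[str, list[Peak]]) -> OverlapMatrix:
    """Pairwise shared-peak counts and min-normalized overlap coefficients.

    coefficient(i, j) = max(shared_i, shared_j) / min(n_i, n_j), clipped to 1,
    so experiments with very different call depths remain comparable. Rows
    are ordered by average-linkage clustering on 1 - coefficient.
    """
    names = list(experiments)
    if len(names) < 2:
        raise ValidationError("overlap_matrix needs at least 2 experiments")
    n = len(names)
    counts = np.zeros((n, n), dtype=int)
    coef = np.eye(n)
    sizes = {k: len(v) for k, v in experiments.items()}
    for name, size in sizes.items():
        if size == 0:
            warnings.warn(f"experiment {name!r} has no peaks; coefficients set to 0")
    for i in range(n):
        counts[i, i] = sizes[names[i]]
        for j in range(i + 1, n):
            a, b = experiments[names[i]], experiments[names[j]]
            sa, sb = count_shared(a, b)
            counts[i, j], counts[j, i] = sa, sb
            denom = min(sizes[names[i]], sizes[names[j]])
            c = min(max(sa, sb) / denom, 1.0) if denom > 0 else 0.0
            coef[i, j] = coef[j, i] = c
    dist = squareform(1.0 - coef, checks=False)
    order = [names[i] for i in leaves_list(average(dist))] if n > 2 else names
    return OverlapMatrix(
        names,
        pd.DataFrame(counts, index=names, columns=names),
        pd.DataFrame(coef, index=names, columns=names),
        order,
    )


@dataclass
class GenomicDistribution:
    counts: dict[str, int]  # promoter, gene_body, intergenic

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, category: str) -> float:
        return self.counts[category] / self.total if self.total else 0.0


def annotate_distribution(
    peaks: list[Peak],
    genes: list[GeneRecord],
    promoter_halfwidth: int = 1000,
    genebody_length: int = 10_000,
) -> GenomicDistribution:
    """Assign each peak by its summit: promoter > gene_body > intergenic.

    Promoter: within +/- promoter_halfwidth of any TSS. Gene body: within
    [TSS, TSS + genebody_length) on the strand-aware downstream side.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    counts = {"promoter": 0, "gene_body": 0, "intergenic": 0}
    for p in peaks:
        s = p.summit
        cat = "intergenic"
        for g in by_chrom.get(p.interval.chrom, []):
            if abs(s - g.tss) <= promoter_halfwidth:
                cat = "promoter"
                break
            if g.strand == "+" and g.tss <= s < g.tss + genebody_length:
                cat = "gene_body"
            elif g.strand == "-" and g.tss - genebody_length < s <= g.tss:
                cat = "gene_body"
        counts[cat] += 1
    return GenomicDistribution(counts)


@dataclass
class TssProfile:
    offsets: np.ndarray  # bp, -window..window step bin
    mean_signal: np.ndarray
    n_genes_used: int
    n_genes_skipped: int


def tss_meta_profile(
    track: SignalTrack,
    genes: list[GeneRecord],
    window: int = 3000,
    bin_width: int = 100,
) -> TssProfile:
    """Mean normalized signal in bins centered at offsets from the TSS.

    Offsets run -window..+window in steps of bin_width (61 points at the
    defaults); minus-strand genes are mirrored so positive offsets are
    downstream of transcription. Genes whose window leaves the chromosome
    are skipped and counted.
    """
    offsets = np.arange(-window, window + 1, bin_width)
    scale = 1e6 / track.total_reads
    half = bin_width // 2
    acc = np.zeros(offsets.size)
    used = skipped = 0
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
        vals = np.array(
            [cov[c - half:c - half + bin_width].mean() for c in centers]
        )
        acc += vals * scale
        used += 1
    if used == 0:
        raise ValidationError("no gene has a complete TSS window")
    return TssProfile(offsets, acc / used, used, skipped)
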