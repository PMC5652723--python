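"""Genome binning, per-million normalization and PCA of binding profiles.

Each ChIP-seq profile is reduced to fixed-width genome bins carrying the
mean per-bp coverage scaled to per-million-reads units; bins that are zero
in every profile are dropped, and the retained bins x profiles matrix is
compared by PCA (profiles as observations, bins as centered features).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from cistrome_compare.formats import SignalTrack, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 100


def bin_signal(
    track: SignalTrack,
    bin_width: int = DEFAULT_BIN_WIDTH,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Per-bin normalized signal: mean per-bp coverage x 1e6 / total_reads.

    Bins tile each chromosome from position 0; the last bin of a chromosome
    may be shorter and is averaged over its actual width.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    lengths = chrom_lengths or track.chrom_lengths
    out: dict[str, np.ndarray] = {}
    scale = 1e6 / track.total_reads
    for chrom, length in lengths.items():
        cov = track.coverage_array(chrom, length)
        n_bins = -(-length // bin_width)
        edges = np.arange(n_bins) * bin_width
        sums = np.add.reduceat(cov, edges)
        widths = np.minimum(edges + bin_width, length) - edges
        out[chrom] = sums / widths * scale
    return out


@dataclass
class BinnedMatrix:
    """Retained non-zero bins x profiles of normalized signal."""

    bins: pd.DataFrame  # columns chrom, start, end
    profiles: list[str]
    values: np.ndarray  # bins x profiles

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.bins), len(self.profiles)):
            raise ValidationError("BinnedMatrix shape mismatch")


def assemble_matrix(
    tracks: dict[str, SignalTrack],
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> BinnedMatrix:
    """Stack binned profiles and keep bins non-zero in at least one profile.

    Chromosomes are intersected across tracks (warning if they differ); a
    fully disjoint chromosome set is an error.
    """
    if len(tracks) < 2:
        raise ValidationError("assemble_matrix needs at least 2 tracks")
    names = list(tracks)
    chrom_sets = [set(t.chrom_lengths) for t in tracks.values()]
    shared = set.intersection(*chrom_sets)
    if not shared:
        raise ValidationError("tracks share no chromosomes")
    if any(cs != shared for cs in chrom_sets):
        warnings.warn("tracks differ in chromosome sets; using the intersection")
    lengths = {
        c: min(t.chrom_lengths[c] for t in tracks.values()) for c in sorted(shared)
    }
    per_chrom_rows = []
    per_chrom_bins = []
    for chrom, length in lengths.items():
        cols = [
            bin_signal(t, bin_width, {chrom: length})[chrom] for t in tracks.values()
        ]
        block = np.column_stack(cols)
        n_bins = block.shape[0]
        starts = np.arange(n_bins) * bin_width
        per_chrom_rows.append(block)
        per_chrom_bins.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + bin_width, length),
                }
            )
        )
    values = np.vstack(per_chrom_rows)
    bins = pd.concat(per_chrom_bins, ignore_index=True)
    keep = (values != 0).any(axis=1)
    if not keep.any():
        warnings.warn("all bins are zero in every profile; matrix is empty")
    return BinnedMatrix(bins[keep].reset_index(drop=True), names, values[keep])


@dataclass
class PcaResult:
    scores: pd.DataFrame  # profiles x k
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        ve = np.asarray(self.variance_explained, dtype=float)
        if np.any(np.diff(ve) > 1e-12) or np.any(ve < -1e-12) or ve.sum() > 1 + 1e-9:
            raise ValidationError("variance_explained must be non-increasing in [0,1]")


def pca(matrix: BinnedMatrix, k: int = 2) -> PcaResult:
    """PCA of profiles over bin features (centered, not scaled).

    Sign convention: the first nonzero loading of each component is made
    positive so results are reproducible across SVD implementations.
    """
    n_profiles = len(matrix.profiles)
    if k >= n_profiles:
        raise ValidationError(f"k={k} must be < number of profiles ({n_profiles})")
    X = matrix.values.T  # profiles x bins
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    for i in range(k):
        loading = model.components_[i]
        nz = np.flatnonzero(np.abs(loading) > 1e-12)
        if nz.size and loading[nz[0]] < 0:
            scores[:, i] *= -1
    score_df = pd.DataFrame(
        scores,
        index=matrix.profiles,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(score_df, model.explained_variance_ratio_.copy())
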