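"""Rank-based per-sample regulatory activity scores with a permutation null.

For one sample, genes are ranked by expression (descending). Two running
cumulative distribution functions are tracked down the ranking — T(i) over
target genes and Non-T(i) over non-targets — and the raw activity score is
the signed maximum deviation T(i) - Non-T(i): positive when targets
concentrate at the top of the ranking, negative at the bottom. The score is
normalized against random reassignments of the target labels ("1000 times
random permutation" by default), giving the individual Regulatory Activity
Score (iRAS) in standard-score units.

Because label permutation destroys any link to the expression values, the
permuted score depends only on where the shuffled labels land in the rank
order — not on the sample — so one permutation ensemble per affinity vector
serves every sample exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cistrome_compare.formats import ExpressionCohort, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000


def _max_signed_deviation(indicator: np.ndarray) -> float:
    """Signed max of T(i) - Non-T(i) for a 0/1 indicator in rank order."""
    k = int(indicator.sum())
    n = indicator.size
    if k == 0 or k == n:
        raise ValidationError("need at least one target and one non-target gene")
    ct = np.cumsum(indicator) / k
    cn = (np.arange(1, n + 1) - np.cumsum(indicator)) / (n - k)
    d = ct - cn
    i = int(np.argmax(np.abs(d)))
    return float(d[i])


def _rank_order(expression: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices sorting genes by expression descending, ties by gene_id."""
    return np.lexsort((gene_ids, -expression))


def base_statistic(affinity: pd.Series, sample: pd.Series) -> float:
    """Raw BASE score of one sample against a 0/1 binding-affinity vector.

    Both series must share the same gene index.
    """
    if not affinity.index.equals(sample.index):
        affinity = affinity.reindex(sample.index)
        if affinity.isna().any():
            raise ValidationError("affinity and sample gene universes differ")
    ind = affinity.to_numpy().astype(bool)
    order = _rank_order(sample.to_numpy(dtype=float), sample.index.to_numpy())
    return _max_signed_deviation(ind[order].astype(np.int8))


def _permutation_scores(
    indicator: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Raw scores of ``n_perm`` random label reassignments (vectorized)."""
    n = indicator.size
    k = int(indicator.sum())
    # random positions for the k labels in each permutation
    keys = rng.random((n_perm, n))
    perm_ind = np.zeros((n_perm, n), dtype=np.int8)
    topk = np.argpartition(keys, k - 1, axis=1)[:, :k]
    np.put_along_axis(perm_ind, topk, 1, axis=1)
    ct = np.cumsum(perm_ind, axis=1) / k
    cn = (np.arange(1, n + 1)[None, :] - np.cumsum(perm_ind, axis=1)) / (n - k)
    d = ct - cn
    idx = np.argmax(np.abs(d), axis=1)
    return d[np.arange(n_perm), idx]


@dataclass
class BaseResult:
    sample_id: str
    raw_score: float
    perm_mean: float
    perm_sd: float
    iras: float


def iras(
    affinity: pd.Series,
    sample: pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    normalization: str = "zscore",
) -> BaseResult:
    """Permutation-normalized activity score for one sample.

    ``normalization='zscore'`` (default) gives
    (raw - perm_mean)/perm_sd; ``'ratio'`` divides the raw score by the mean
    absolute value of same-sign permutation scores.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    raw = base_statistic(affinity, sample)
    ind = affinity.reindex(sample.index).to_numpy().astype(np.int8)
    rng = np.random.default_rng(seed)
    perm = _permutation_scores(ind, n_perm, rng)
    return _normalize(str(sample.name or "sample"), raw, perm, normalization)


def _normalize(
    sample_id: str, raw: float, perm: np.ndarray, normalization: str
) -> BaseResult:
    mean = float(perm.mean())
    sd = float(perm.std(ddof=0))
    if sd == 0:
        raise ValidationError("degenerate permutation null (sd = 0)")
    if normalization == "zscore":
        score = (raw - mean) / sd
    elif normalization == "ratio":
        same_sign = perm[np.sign(perm) == np.sign(raw)]
        denom = float(np.abs(same_sign).mean()) if same_sign.size else sd
        score = raw / denom
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")
    return BaseResult(sample_id, raw, mean, sd, float(score))


def iras_matrix(
    affinities: pd.DataFrame,
    cohort: ExpressionCohort,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    normalization: str = "zscore",
) -> pd.DataFrame:
    """samples x cell-lines iRAS table.

    ``affinities`` is a genes x cell-lines 0/1 DataFrame sharing the
    cohort's gene universe. One permutation ensemble is drawn per cell line
    (seeded from ``seed`` and the column position) and reused across
    samples, which is exact because permuted scores are sample-independent.
    """
    expr = cohort.expression
    if not affinities.index.equals(expr.index):
        affinities = affinities.reindex(expr.index)
        if affinities.isna().any().any():
            raise ValidationError("affinity universe does not match cohort genes")
    gene_ids = expr.index.to_numpy()
    values = expr.to_numpy(dtype=float)
    out = {}
    for line in affinities.columns:
        ind = affinities[line].to_numpy().astype(np.int8)
        # seeding on (seed, n_targets) makes duplicated affinity columns
        # yield identical scores while distinct set sizes get fresh draws
        rng = np.random.default_rng([seed, int(ind.sum())])
        perm = _permutation_scores(ind, n_perm, rng)
        mean, sd = float(perm.mean()), float(perm.std(ddof=0))
        if sd == 0:
            raise ValidationError(f"degenerate permutation null for {line!r}")
        scores = []
        for s_idx in range(values.shape[1]):
            order = _rank_order(values[:, s_idx], gene_ids)
            raw = _max_signed_deviation(ind[order])
            res = _normalize(str(expr.columns[s_idx]), raw, perm, normalization)
            scores.append(res.iras)
        out[f"iRAS_{line}"] = scores
    return pd.DataFrame(out, index=pd.Index(expr.columns, name="sample_id"))
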