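"""Reference-gene stability ranking (geNorm) and count normalization.

The study panel carries ~40 candidate reference genes.  The geNorm M value
of candidate j is the mean, over all other candidates k, of the standard
deviation across samples of log2(x_j / x_k); stable references have small
M.  The iterative variant repeatedly removes the least stable candidate and
recomputes, so that the genes removed last are the most stable ones.

Counts are then normalized against the selected references by per-sample
scale factors that equalize the geometric mean of the reference genes
across samples, centred so that the grand mean of those geometric means is
preserved (the counts stay commensurate with the raw scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, ExpressionMatrix

__all__ = [
    "StabilityRanking",
    "genorm_stability",
    "select_reference_genes",
    "normalize",
    "log_transform",
]


@dataclass
class StabilityRanking:
    """geNorm stability result.

    ``m_values`` holds the M value computed from the full candidate set;
    ``removal_order`` lists candidates from least to most stable under
    iterative removal (the last entries are the genes a geNorm selection
    keeps).  ``iterative_m`` records the M value each gene had at the
    round in which it was removed.
    """

    m_values: pd.Series
    removal_order: list[str]
    iterative_m: pd.Series
    mode: str = "iterative"


def _pairwise_m(logx: np.ndarray) -> np.ndarray:
    """M value per gene: mean over other genes of SD of pairwise log-ratios.

    ``logx`` is genes x samples on the log2 scale.
    """
    g = logx.shape[0]
    m = np.empty(g)
    for j in range(g):
        diffs = logx[j][None, :] - logx  # g x s log-ratios
        sds = diffs.std(axis=1, ddof=1)
        m[j] = (sds.sum() - sds[j]) / (g - 1)  # exclude self (sd 0)
    return m


def genorm_stability(
    ref_counts: pd.DataFrame, mode: str = "iterative"
) -> StabilityRanking:
    """Rank candidate reference genes by geNorm expression stability.

    Parameters
    ----------
    ref_counts : DataFrame
        Candidate-reference genes x samples, strictly positive values.
    mode : {"iterative", "single_pass"}
        ``iterative`` (the published geNorm procedure) repeatedly drops the
        gene with the largest M and recomputes; ``single_pass`` ranks by the
        one-shot M values.
    """
    if ref_counts.shape[0] < 3:
        raise ValueError("geNorm requires at least 3 candidate genes")
    if ref_counts.shape[1] < 2:
        raise ValueError("geNorm requires at least 2 samples")
    vals = ref_counts.to_numpy(dtype=float)
    if (vals <= 0).any():
        i, j = np.argwhere(vals <= 0)[0]
        raise ValueError(
            "non-positive count for candidate reference gene "
            f"{ref_counts.index[i]!r} in sample {ref_counts.columns[j]!r}; "
            "offset or exclude it first"
        )
    if mode not in ("iterative", "single_pass"):
        raise ValueError(f"unknown geNorm mode {mode!r}")
    genes = [str(g) for g in ref_counts.index]
    logx = np.log2(vals)
    m_full = pd.Series(_pairwise_m(logx), index=genes, name="M")

    if mode == "single_pass":
        order = list(m_full.sort_values(ascending=False, kind="stable").index)
        # deterministic tie-break: equal M sorted by gene id
        order = sorted(order, key=lambda g: (-m_full[g], g))
        iterative_m = m_full.copy()
        return StabilityRanking(m_full, order, iterative_m, mode)

    remaining = list(range(len(genes)))
    removal: list[str] = []
    m_at_removal: dict[str, float] = {}
    while len(remaining) > 2:
        sub = logx[remaining]
        m = _pairwise_m(sub)
        # largest M removed first; ties broken by gene identifier
        worst = max(range(len(remaining)), key=lambda i: (m[i], genes[remaining[i]]))
        g = genes[remaining[worst]]
        removal.append(g)
        m_at_removal[g] = float(m[worst])
        remaining.pop(worst)
    # final pair is indistinguishable by M; order by identifier
    last = sorted(genes[i] for i in remaining)
    sub = logx[remaining]
    m = _pairwise_m(sub)
    for i, idx in enumerate(remaining):
        m_at_removal[genes[idx]] = float(m[i])
    removal.extend(last)
    iterative_m = pd.Series({g: m_at_removal[g] for g in genes}, name="M")
    return StabilityRanking(m_full, removal, iterative_m, mode)


def select_reference_genes(ranking: StabilityRanking, n_keep: int) -> list[str]:
    """Keep the ``n_keep`` most stable candidates (removed last)."""
    n = len(ranking.removal_order)
    if n_keep > n:
        raise ValueError(f"n_keep={n_keep} exceeds {n} candidates")
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    kept = ranking.removal_order[n - n_keep:]
    return sorted(kept)


def _geometric_means(values: pd.DataFrame) -> pd.Series:
    return pd.Series(
        np.exp(np.log(values.to_numpy(dtype=float)).mean(axis=0)),
        index=values.columns,
    )


def scale_factors(
    cm: CountMatrix, refs, pseudocount: float = 1.0
) -> pd.Series:
    """Per-sample normalization factors from reference-gene geometric means.

    factor_s = mean_s'(geomean of refs in s') / (geomean of refs in s), so
    multiplying sample s by factor_s equalizes reference geometric means
    across samples while preserving their grand mean.
    """
    refs = sorted(set(refs))
    missing = set(refs) - set(cm.genes)
    if missing:
        raise ValueError(f"reference genes not in matrix: {sorted(missing)}")
    sub = cm.counts.loc[refs].astype(float)
    if (sub.to_numpy() <= 0).any():
        warnings.warn(
            "zero counts among reference genes replaced by pseudocount "
            f"{pseudocount} before geometric means",
            stacklevel=2,
        )
        sub = sub.where(sub > 0, pseudocount)
        if (sub.to_numpy() <= 0).any():
            raise ValueError("reference counts remain non-positive")
    gm = _geometric_means(sub)
    return gm.mean() / gm


def normalize(
    cm: CountMatrix, refs, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Scale every sample by its reference-gene factor.

    Returns a real-valued matrix on the raw-count scale (not logged).
    """
    factors = scale_factors(cm, refs, pseudocount)
    values = cm.counts.astype(float) * factors
    return ExpressionMatrix(values, is_log2=False)


def log_transform(
    m: ExpressionMatrix | pd.DataFrame, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Elementwise log2(x + pseudocount)."""
    values = m.values if isinstance(m, ExpressionMatrix) else m
    values = pd.DataFrame(values).astype(float)
    shifted = values + pseudocount
    if (shifted.to_numpy() <= 0).any():
        raise ValueError("values + pseudocount must be positive for log2")
    return ExpressionMatrix(np.log2(shifted), is_log2=True)
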