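"""Pathway dysregulation scores and pathway-level significance.

A pathway is scored per sample by the first principal component of its
genes' log2 expression after (i) centering each gene at the adjacent-normal
baseline mean and (ii) dividing by the larger of the gene's standard
deviation or 0.05 (the SD floor keeps near-constant genes from blowing up).
The PC sign is oriented so that the mean tumor score is at least the mean
baseline score.

Two measures of pathway-level evidence are computed: a mixed-model p-value
for the score (same regression as the gene-level differential expression),
and the "global significance" sqrt(mean(t^2)) of the pathway genes' Wald
statistics from the gene-level analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import _design_frame
from .io import ExpressionMatrix, SampleTable
from .lmm import NestedLMM, lrt_focus_variance

__all__ = [
    "PathwayScore",
    "pathway_score",
    "pathway_differential",
    "global_significance",
    "significance_plot_table",
]

SD_FLOOR = 0.05


@dataclass
class PathwayScore:
    """Per-sample dysregulation score for one pathway."""

    pathway: str
    scores: pd.Series  # indexed by sample
    loadings: pd.Series  # PC1 gene loadings (unit norm)
    explained_fraction: float
    orientation: int  # +1 or -1, applied to the raw PC1

    @property
    def genes(self) -> list[str]:
        return list(self.loadings.index)


def pathway_score(
    logm: ExpressionMatrix,
    genes,
    baseline,
    name: str = "pathway",
    sd_floor: float = SD_FLOOR,
    sd_scope: str = "all",
) -> PathwayScore:
    """Score samples on one pathway via scaled first principal component.

    Parameters
    ----------
    logm : ExpressionMatrix
        log2 expression, genes x samples.
    genes : iterable of str
        Pathway membership; genes absent from the matrix are dropped with a
        warning.
    baseline : iterable of str
        Adjacent-normal sample identifiers used as the reference level.
    sd_scope : {"all", "baseline"}
        Whether the SD in max(SD, floor) is computed across all samples or
        baseline samples only.
    """
    genes = sorted(set(genes))
    present = [g for g in genes if g in set(logm.genes)]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(
            f"pathway {name!r}: dropping genes absent from the matrix: "
            f"{missing}",
            stacklevel=2,
        )
    if len(present) < 2:
        raise ValueError(f"pathway {name!r} has fewer than 2 usable genes")
    baseline = [str(s) for s in baseline]
    if not baseline:
        raise ValueError("at least one baseline (normal) sample is required")
    bad = sorted(set(baseline) - set(logm.samples))
    if bad:
        raise ValueError(f"baseline samples not in matrix: {bad}")

    sub = logm.values.loc[present]  # genes x samples
    base_mean = sub[baseline].mean(axis=1)
    if sd_scope == "all":
        sd = sub.std(axis=1, ddof=1)
    elif sd_scope == "baseline":
        sd = sub[baseline].std(axis=1, ddof=1)
    else:
        raise ValueError(f"unknown sd_scope {sd_scope!r}")
    scale = sd.clip(lower=sd_floor)
    scaled = sub.sub(base_mean, axis=0).div(scale, axis=0)

    # PC1 of the samples in the scaled gene space, without re-centering:
    # the baseline-mean subtraction above is the only centering applied.
    M = scaled.to_numpy().T  # samples x genes
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    raw = U[:, 0] * S[0]
    loadings = Vt[0]
    total = float((S**2).sum())
    explained = float(S[0] ** 2 / total) if total > 0 else 0.0

    scores = pd.Series(raw, index=logm.samples, name=name)
    tumor_samples = [s for s in logm.samples if s not in set(baseline)]
    tumor_mean = scores[tumor_samples].mean() if tumor_samples else 0.0
    base_score_mean = scores[baseline].mean()
    if tumor_mean > base_score_mean:
        sign = 1
    elif tumor_mean < base_score_mean:
        sign = -1
    else:  # deterministic tie-break: first gene loads positively
        sign = 1 if loadings[0] >= 0 else -1
    return PathwayScore(
        pathway=name,
        scores=sign * scores,
        loadings=pd.Series(sign * loadings, index=present),
        explained_fraction=explained,
        orientation=sign,
    )


def pathway_differential(
    scores: dict[str, PathwayScore] | list[PathwayScore],
    st: SampleTable,
    contrast: str = "tumor_vs_normal",
    lrt_convention: str = "chisq1",
) -> pd.DataFrame:
    """Mixed-model p-value per pathway for the requested contrast.

    ``tumor_vs_normal`` applies the gene-level DE regression (tissue fixed
    effect, patient + focus random intercepts) with the pathway score as
    the response.  ``between_foci`` fits tumor samples only and tests
    sigma_F = 0 by a boundary LRT.
    """
    if isinstance(scores, dict):
        scores = list(scores.values())
    rows = []
    for ps in scores:
        score = ps.scores
        if contrast == "tumor_vs_normal":
            sm = ExpressionMatrix(
                pd.DataFrame([score.to_numpy()], index=["__score__"],
                             columns=score.index),
                is_log2=False,
            )
            meta = _design_frame(sm, st)
            if float(score.std()) == 0.0:
                rows.append((ps.pathway, 1.0))
                continue
            X = np.column_stack(
                [np.ones(len(meta)), meta["tissue_tumor"].to_numpy()]
            )
            model = NestedLMM(
                score.loc[meta.index], X, meta["patient_id"],
                meta["focus_id"], exog_names=["Intercept", "tissue_tumor"],
            )
            res = model.fit(method="REML")
            p = float(res.pvalues()["tissue_tumor"])
        elif contrast == "between_foci":
            tum = st.tumor.set_index("sample_id")
            ids = [s for s in score.index if s in tum.index]
            y = score.loc[ids]
            if float(y.std()) == 0.0:
                rows.append((ps.pathway, 1.0))
                continue
            meta = tum.loc[ids]
            X = np.ones((len(ids), 1))
            model = NestedLMM(
                y, X, meta["patient_id"], meta["focus_id"],
                exog_names=["Intercept"],
            )
            full = model.fit(method="REML")
            red = model.fit(method="REML", include_focus=False)
            p = lrt_focus_variance(full, red, lrt_convention)
        else:
            raise ValueError(f"unknown contrast {contrast!r}")
        rows.append((ps.pathway, p))
    return pd.DataFrame(rows, columns=["pathway", "p"])


def global_significance(t_stats) -> float:
    """Root mean square of the per-gene t statistics for one pathway."""
    t = np.asarray(t_stats, dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no finite t statistics supplied")
    return float(np.sqrt(np.mean(t**2)))


def significance_plot_table(
    pathway_p: pd.DataFrame,
    de_records: pd.DataFrame,
    panel_pathways: dict[str, set[str]],
) -> pd.DataFrame:
    """Table of (pathway, -log10 score p, global significance) for plotting.

    ``pathway_p`` is the output of :func:`pathway_differential`;
    ``de_records`` the gene-level differential-expression frame (for its
    ``t`` column); ``panel_pathways`` maps pathway -> gene set.
    """
    t_by_gene = de_records.set_index("gene")["t"]
    rows = []
    for _, row in pathway_p.iterrows():
        genes = [
            g for g in panel_pathways.get(row["pathway"], set())
            if g in t_by_gene.index
        ]
        gs = global_significance(t_by_gene.loc[genes]) if genes else np.nan
        rows.append(
            (row["pathway"], -np.log10(max(row["p"], 1e-300)), gs)
        )
    return pd.DataFrame(
        rows, columns=["pathway", "neg_log10_p", "global_significance"]
    )
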