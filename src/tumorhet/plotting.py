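"""Figures: per-gene expression profiles, pathway significance scatter,
per-gene copy-number range plots.

All functions return a matplotlib Figure; callers decide about saving.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402  (headless backend before pyplot import)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .copynumber import CNMatrix
from .io import ExpressionMatrix, SampleTable

__all__ = [
    "make_gene_profile_plot",
    "make_significance_plot",
    "make_cn_range_plot",
]


def _ordered_tumor_meta(st: SampleTable) -> pd.DataFrame:
    """Tumor samples ordered by patient, then focus size descending."""
    tum = st.tumor.copy()
    if "focus_size_cm" in tum.columns and tum["focus_size_cm"].notna().any():
        tum["_size"] = tum["focus_size_cm"].fillna(0.0)
    else:
        tum["_size"] = 0.0
    return tum.sort_values(
        ["patient_id", "_size", "focus_id", "punch_id"],
        ascending=[True, False, True, True],
    )


def make_gene_profile_plot(
    logm: ExpressionMatrix, st: SampleTable, gene: str
):
    """Log2 expression of one gene, punches grouped by focus within patient.

    Foci are ordered by size descending (largest focus leftmost within each
    patient group); adjacent-normal punches, when present, are shown as a
    final group.
    """
    if gene not in set(logm.genes):
        raise KeyError(f"gene {gene!r} not in expression matrix")
    tum = _ordered_tumor_meta(st)
    tum = tum[tum["sample_id"].isin(set(logm.samples))]
    values = logm.values.loc[gene]

    fig, ax = plt.subplots(figsize=(10, 4))
    xticks, xlabels, x = [], [], 0
    colors = plt.cm.tab20(np.linspace(0, 1, 20))
    for pi, (pat, psub) in enumerate(tum.groupby("patient_id", sort=True)):
        start = x
        for foc, fsub in psub.groupby("focus_id", sort=False):
            y = values[fsub["sample_id"]].to_numpy()
            ax.plot(
                np.arange(x, x + len(y)), y, "o",
                color=colors[pi % 20], markersize=5,
            )
            x += len(y)
        xticks.append((start + x - 1) / 2.0)
        xlabels.append(pat)
        ax.axvline(x - 0.5, color="0.85", lw=0.8)
    normals = st.normal[st.normal["sample_id"].isin(set(logm.samples))]
    if len(normals):
        y = values[normals["sample_id"]].to_numpy()
        ax.plot(np.arange(x, x + len(y)), y, "s", color="0.3", markersize=5)
        xticks.append(x + (len(y) - 1) / 2.0)
        xlabels.append("normal")
    ax.set_xticks(xticks)
    ax.set_xticklabels(xlabels, rotation=45, ha="right")
    ax.set_ylabel("log2 expression")
    ax.set_title(gene)
    fig.tight_layout()
    return fig


def make_significance_plot(table: pd.DataFrame):
    """Scatter of global significance vs -log10 pathway-score p-value."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(
        table["neg_log10_p"], table["global_significance"], color="tab:blue"
    )
    for _, row in table.iterrows():
        ax.annotate(
            str(row["pathway"]),
            (row["neg_log10_p"], row["global_significance"]),
            fontsize=8, xytext=(3, 3), textcoords="offset points",
        )
    ax.set_xlabel("-log10 pathway score p-value")
    ax.set_ylabel("global significance  sqrt(mean t^2)")
    fig.tight_layout()
    return fig


def make_cn_range_plot(cn: CNMatrix, st: SampleTable, gene: str):
    """Min/max/mean copy number per focus for one gene across patients."""
    if gene not in set(cn.genes):
        raise KeyError(f"gene {gene!r} not in copy-number matrix")
    tum = _ordered_tumor_meta(st)
    tum = tum[tum["sample_id"].isin(set(cn.samples))]
    vals = cn.cn.loc[gene]

    fig, ax = plt.subplots(figsize=(10, 4))
    labels, x = [], 0
    for (pat, foc), sub in tum.groupby(["patient_id", "focus_id"], sort=True):
        v = vals[sub["sample_id"]].to_numpy()
        mean = v.mean()
        color = (
            "tab:red" if mean >= 3.0 else "tab:blue" if mean < 1.5 else "0.4"
        )
        ax.vlines(x, v.min(), v.max(), color=color, lw=3)
        ax.plot([x - 0.25, x + 0.25], [mean, mean], color=color, lw=2)
        labels.append(f"{pat}_{foc}")
        x += 1
    ax.axhline(2.0, color="0.8", ls="--", lw=1)
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("copy number")
    ax.set_title(gene)
    fig.tight_layout()
    return fig
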