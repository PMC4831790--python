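"""Per-gene tumor vs adjacent-normal differential expression.

Each gene's log2 expression is modelled with the nested mixed model: a
fixed tissue effect (tumor vs normal) plus patient and focus random
intercepts.  The fold change is 2**beta_tissue and the p-value is a Wald
test of beta_tissue = 0.  Normal samples have no focus, so each one is
given its own singleton focus level; its extra variability then loads onto
the focus + residual components consistently for every gene.

Multiplicity is handled by Holm step-down adjustment and Benjamini-
Hochberg q-values, each applied across all genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleTable
from .lmm import NestedLMM

__all__ = [
    "differential_expression",
    "holm_adjust",
    "bh_qvalues",
    "filter_de",
]


def _check_pvalues(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjusted p-values (order-preserving)."""
    p = _check_pvalues(p)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (FDR estimates)."""
    p = _check_pvalues(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _design_frame(logm: ExpressionMatrix, st: SampleTable) -> pd.DataFrame:
    """Align sample metadata with the expression columns; singleton foci for
    normals."""
    meta = st.data.set_index("sample_id").loc[list(logm.samples)].copy()
    # samples without a focus (adjacent normals) get singleton focus levels
    no_focus = meta["focus_id"] == ""
    meta.loc[no_focus, "focus_id"] = [
        f"__singleton__{s}" for s in meta.index[no_focus]
    ]
    meta["tissue_tumor"] = (meta["tissue"] == "tumor").astype(float)
    return meta


def differential_expression(
    logm: ExpressionMatrix,
    st: SampleTable,
    include_grade: bool = False,
    use_t: bool = False,
) -> pd.DataFrame:
    """Tumor vs normal mixed-model differential expression for every gene.

    Returns a frame with one row per gene: ``log2fc``, ``FC`` (2**log2fc),
    ``t`` (Wald statistic), ``p``, ``p_holm``, ``q`` and ``direction``.
    Genes with zero variance are reported as null (FC = 1, p = 1).
    """
    if not logm.is_log2:
        raise ValueError("differential expression expects log2 expression")
    meta = _design_frame(logm, st)
    n_tumor = int(meta["tissue_tumor"].sum())
    if n_tumor == 0 or n_tumor == len(meta):
        raise ValueError("need at least one tumor and one normal sample")

    cols = [np.ones(len(meta)), meta["tissue_tumor"].to_numpy()]
    names = ["Intercept", "tissue_tumor"]
    if include_grade:
        dummies = pd.get_dummies(
            meta["grade"].astype(str), prefix="grade",
            drop_first=True,
        )
        for d in dummies.columns:
            cols.append(dummies[d].to_numpy(dtype=float))
            names.append(d)
    X = np.column_stack(cols)

    records = []
    base_model = None
    for gene in logm.genes:
        y = logm.values.loc[gene].to_numpy(dtype=float)
        if np.ptp(y) == 0.0:
            records.append((gene, 0.0, 1.0, 0.0, 1.0))
            continue
        if base_model is None:
            base_model = NestedLMM(
                y, X, meta["patient_id"], meta["focus_id"], exog_names=names
            )
            model = base_model
        else:
            model = _rebind(base_model, y)
        res = model.fit(method="REML")
        beta = float(res.params["tissue_tumor"])
        t = float(res.tvalues["tissue_tumor"])
        p = float(res.pvalues(use_t=use_t)["tissue_tumor"])
        records.append((gene, beta, 2.0**beta, t, p))

    out = pd.DataFrame(
        records, columns=["gene", "log2fc", "FC", "t", "p"]
    )
    out["p_holm"] = holm_adjust(out["p"].to_numpy())
    out["q"] = bh_qvalues(out["p"].to_numpy())
    out["direction"] = np.where(out["FC"] > 1.0, "up", "down")
    out.loc[out["FC"] == 1.0, "direction"] = "none"
    return out


def _rebind(model: NestedLMM, y: np.ndarray) -> NestedLMM:
    """Cheap copy of a model with a new response, reusing the design."""
    new = object.__new__(NestedLMM)
    new.__dict__ = dict(model.__dict__)
    new.endog = np.asarray(y, dtype=float).ravel()
    return new


def filter_de(
    records: pd.DataFrame,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Keep genes with q < q_max and FC strictly outside [fc_down, fc_up]."""
    if not fc_down < 1.0 < fc_up:
        raise ValueError("need fc_down < 1 < fc_up")
    keep = (records["q"] < q_max) & (
        (records["FC"] > fc_up) | (records["FC"] < fc_down)
    )
    return records[keep].reset_index(drop=True)
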