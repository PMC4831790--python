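"""Three-level variance decomposition of tumor expression heterogeneity.

For each gene, a REML fit of log2 expression on tumor punches with grade as
a fixed effect and patient + focus random intercepts yields sigma_P,
sigma_F and sigma_IT.  Each squared component, as a percentage of the total
variance, is the corresponding heterogeneity share:

    HET.P  = 100 * sigma_P^2  / (sigma_P^2 + sigma_F^2 + sigma_IT^2)
    HET.F  = 100 * sigma_F^2  / (sigma_P^2 + sigma_F^2 + sigma_IT^2)
    HET.IT = 100 * sigma_IT^2 / (sigma_P^2 + sigma_F^2 + sigma_IT^2)

HET.F measures within-patient focus-to-focus heterogeneity — the study's
headline quantity — and is tested by a boundary likelihood-ratio test of
sigma_F = 0; HET.P is tested analogously by dropping the patient component.
Holm and BH adjustments are applied across genes separately per test
family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import _rebind, bh_qvalues, holm_adjust
from .io import ExpressionMatrix, SampleTable
from .lmm import NestedLMM, lrt_variance_component

__all__ = [
    "het_decomposition",
    "heterogeneity_analysis",
    "rank_by_patient_heterogeneity",
]


def het_decomposition(
    sigma_P: float, sigma_F: float, sigma_IT: float
) -> tuple[float, float, float]:
    """Percent variance shares (HET.P, HET.F, HET.IT) from the three sigmas.

    Returns NaNs when all sigmas are zero (no variance to decompose).
    """
    if min(sigma_P, sigma_F, sigma_IT) < 0:
        raise ValueError("standard deviations must be non-negative")
    total = sigma_P**2 + sigma_F**2 + sigma_IT**2
    if total == 0.0:
        return (np.nan, np.nan, np.nan)
    return (
        100.0 * sigma_P**2 / total,
        100.0 * sigma_F**2 / total,
        100.0 * sigma_IT**2 / total,
    )


def heterogeneity_analysis(
    logm: ExpressionMatrix,
    st: SampleTable,
    lrt_convention: str = "chisq1",
    include_grade: bool = True,
) -> pd.DataFrame:
    """Per-gene variance decomposition over tumor punches.

    Uses tumor samples only (grade is a tumor attribute and normals carry
    no focus).  Requires at least two patients with two or more foci so
    that sigma_F is informed.  Returns one row per gene with the sigmas,
    HET percentages, LRT p-values for sigma_P = 0 and sigma_F = 0, and
    Holm/BH adjusted versions of each (adjusted per family).
    """
    if not logm.is_log2:
        raise ValueError("heterogeneity analysis expects log2 expression")
    tum = st.tumor
    tumor_ids = [s for s in logm.samples if s in set(tum["sample_id"])]
    if len(tumor_ids) < 4:
        raise ValueError("too few tumor samples for a variance decomposition")
    meta = tum.set_index("sample_id").loc[tumor_ids]
    foci_per_patient = meta.groupby("patient_id")["focus_id"].nunique()
    if (foci_per_patient >= 2).sum() < 1:
        raise ValueError(
            "no patient has >= 2 foci: between-foci variance is not estimable"
        )

    cols = [np.ones(len(meta))]
    names = ["Intercept"]
    if include_grade:
        dummies = pd.get_dummies(
            meta["grade"].astype(str), prefix="grade",
            drop_first=True,
        )
        for d in dummies.columns:
            col = dummies[d].to_numpy(dtype=float)
            if col.std() > 0:  # drop constant grade dummies
                cols.append(col)
                names.append(d)
    X = np.column_stack(cols)

    base = None
    rows = []
    values = logm.values[tumor_ids]
    for gene in logm.genes:
        y = values.loc[gene].to_numpy(dtype=float)
        if np.ptp(y) == 0.0:
            rows.append((gene, 0.0, 0.0, 0.0, np.nan, np.nan, np.nan, 1.0, 1.0))
            continue
        if base is None:
            base = NestedLMM(
                y, X, meta["patient_id"], meta["focus_id"], exog_names=names
            )
            model = base
        else:
            model = _rebind(base, y)
        full = model.fit(method="REML")
        red_f = model.fit(method="REML", include_focus=False)
        red_p = model.fit(method="REML", include_patient=False)
        p_f = lrt_variance_component(full, red_f, lrt_convention)
        p_p = lrt_variance_component(full, red_p, lrt_convention)
        het = het_decomposition(full.sigma_P, full.sigma_F, full.sigma_IT)
        rows.append(
            (gene, full.sigma_P, full.sigma_F, full.sigma_IT, *het, p_p, p_f)
        )

    out = pd.DataFrame(
        rows,
        columns=[
            "gene", "sigma_P", "sigma_F", "sigma_IT",
            "HET.P", "HET.F", "HET.IT", "pval.P", "pval.F",
        ],
    )
    out["pval.P.holm"] = holm_adjust(out["pval.P"].to_numpy())
    out["q.P"] = bh_qvalues(out["pval.P"].to_numpy())
    out["pval.F.holm"] = holm_adjust(out["pval.F"].to_numpy())
    out["q.F"] = bh_qvalues(out["pval.F"].to_numpy())
    return out


def rank_by_patient_heterogeneity(
    records: pd.DataFrame, threshold: float = 80.0
) -> pd.DataFrame:
    """Genes whose between-patient share HET.P strictly exceeds ``threshold``,
    sorted descending."""
    keep = records[records["HET.P"] > threshold]
    return keep.sort_values("HET.P", ascending=False, kind="stable").reset_index(
        drop=True
    )
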