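"""NanoString-style gene copy-number estimation from probe counts.

The CNV panel carries 2-3 probes per target gene plus a set of invariant
control probes.  Samples are first depth-normalized so the invariant
probes' geometric means agree, then the copy number of gene g in sample s
is estimated as

    CN = 2 * mean(probe counts of g in s) / mean(probe counts of g across
         the adjacent-normal reference samples),

i.e. the diploid baseline is set by the adjacent-normal reference.  Calls
use a lower (exclusive) deletion bound and an upper (inclusive)
amplification bound.  A qPCR delta-delta-CT estimator and a copy-number /
expression Spearman correlation round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleTable, _check_unique

__all__ = [
    "ProbeCountMatrix",
    "CNMatrix",
    "read_probe_counts",
    "estimate_copy_number",
    "call_copy_state",
    "focus_consistency",
    "ddct_copy_number",
    "cn_expression_correlation",
]


@dataclass
class ProbeCountMatrix:
    """Probe x sample counts with probe->gene mapping and invariant set."""

    counts: pd.DataFrame  # probes x samples, non-negative reals
    probe_gene: pd.Series  # gene per target probe (indexed by probe)
    probe_class: pd.Series  # {"target", "invariant"} per probe

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "probe identifiers")
        _check_unique(self.counts.columns, "sample identifiers")
        arr = self.counts.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("probe counts must be non-negative")
        self.counts = self.counts.astype(float)
        cls = self.probe_class.reindex(self.counts.index)
        if cls.isna().any():
            raise ValueError("every probe needs a class (target/invariant)")
        bad = cls[~cls.isin(["target", "invariant"])]
        if len(bad):
            raise ValueError(f"unknown probe class {bad.iloc[0]!r}")
        self.probe_class = cls
        if not (cls == "invariant").any():
            raise ValueError("invariant control probe set is empty")
        genes = self.probe_gene.reindex(self.counts.index[cls == "target"])
        if genes.isna().any():
            raise ValueError("every target probe needs a gene annotation")
        self.probe_gene = genes
        per_gene = genes.groupby(genes).size()
        single = per_gene[per_gene < 2]
        if len(single):
            warnings.warn(
                f"genes with a single probe: {sorted(single.index)}",
                stacklevel=2,
            )

    @property
    def genes(self) -> list[str]:
        return sorted(self.probe_gene.unique())

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def invariant_probes(self) -> list[str]:
        return list(self.counts.index[self.probe_class == "invariant"])


def read_probe_counts(path) -> ProbeCountMatrix:
    """Read probe-count CSV: probe_id, gene, class {target, invariant},
    then one column per sample."""
    df = pd.read_csv(path, index_col=0)
    for c in ("gene", "class"):
        if c not in df.columns:
            raise ValueError(f"probe-count file missing column {c!r}")
    cls = df["class"].astype(str).str.strip()
    gene = df["gene"].astype(str).str.strip()
    counts = df.drop(columns=["gene", "class"])
    return ProbeCountMatrix(counts, gene[cls == "target"], cls)


@dataclass
class CNMatrix:
    """Gene x sample estimated copy number (positive reals)."""

    cn: pd.DataFrame
    normal_ref: list[str]

    @property
    def genes(self) -> list[str]:
        return list(self.cn.index)

    @property
    def samples(self) -> list[str]:
        return list(self.cn.columns)


def _invariant_factors(
    pm: ProbeCountMatrix, method: str = "geometric"
) -> pd.Series:
    inv = pm.counts.loc[pm.invariant_probes]
    if (inv.to_numpy() <= 0).any():
        raise ValueError("invariant control probes must be positive")
    if method == "geometric":
        level = np.exp(np.log(inv).mean(axis=0))
    elif method == "arithmetic":
        level = inv.mean(axis=0)
    else:
        raise ValueError(f"unknown invariant normalization {method!r}")
    return level.mean() / level


def estimate_copy_number(
    pm: ProbeCountMatrix,
    normal_ref,
    invariant_stat: str = "geometric",
) -> CNMatrix:
    """Estimate per-gene, per-sample copy number against a normal reference.

    ``normal_ref`` lists the adjacent-normal sample identifiers whose mean
    probe counts define the diploid (CN = 2) baseline.
    """
    normal_ref = [str(s) for s in normal_ref]
    if not normal_ref:
        raise ValueError("normal reference sample set is empty")
    missing = sorted(set(normal_ref) - set(pm.samples))
    if missing:
        raise ValueError(f"normal reference samples not in matrix: {missing}")
    factors = _invariant_factors(pm, invariant_stat)
    normed = pm.counts * factors

    target = normed.loc[pm.probe_gene.index]
    by_gene = target.groupby(pm.probe_gene).mean()  # gene x sample probe means
    ref_mean = by_gene[normal_ref].mean(axis=1)
    zero_ref = ref_mean[ref_mean == 0]
    if len(zero_ref):
        raise ValueError(
            "zero normal-reference mean for genes: "
            f"{sorted(zero_ref.index)}"
        )
    cn = 2.0 * by_gene.div(ref_mean, axis=0)
    return CNMatrix(cn, normal_ref)


def call_copy_state(
    cn: CNMatrix, del_thresh: float = 1.5, amp_thresh: float = 3.0
) -> pd.DataFrame:
    """Call deletion (CN < del_thresh), amplification (CN >= amp_thresh) or
    neutral per gene and sample."""
    if not del_thresh < 2.0 < amp_thresh:
        raise ValueError("need del_thresh < 2 < amp_thresh")
    calls = pd.DataFrame(
        "neutral", index=cn.cn.index, columns=cn.cn.columns
    )
    calls = calls.mask(cn.cn < del_thresh, "deletion")
    calls = calls.mask(cn.cn >= amp_thresh, "amplification")
    return calls


def focus_consistency(
    cn: CNMatrix,
    st: SampleTable,
    del_thresh: float = 1.5,
    amp_thresh: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-focus copy-number ranges and per-patient call concordance.

    Returns ``(focus_summary, patient_concordance)``: the first has one row
    per (gene, patient, focus) with min/max/mean CN and the focus-level
    call (from the mean); the second one row per (gene, patient) with the
    set of focus calls and whether they agree across foci.
    """
    calls = call_copy_state(cn, del_thresh, amp_thresh)
    tum = st.tumor.set_index("sample_id")
    ids = [s for s in cn.samples if s in tum.index]
    rows = []
    for gene in cn.genes:
        vals = cn.cn.loc[gene, ids]
        for (pat, foc), sub in tum.loc[ids].groupby(["patient_id", "focus_id"]):
            v = vals[sub.index]
            mean_cn = float(v.mean())
            if mean_cn < del_thresh:
                call = "deletion"
            elif mean_cn >= amp_thresh:
                call = "amplification"
            else:
                call = "neutral"
            punch_calls = calls.loc[gene, sub.index]
            rows.append(
                (
                    gene, pat, foc, float(v.min()), float(v.max()), mean_cn,
                    call, bool((punch_calls == call).all()),
                )
            )
    focus_summary = pd.DataFrame(
        rows,
        columns=[
            "gene", "patient_id", "focus_id", "cn_min", "cn_max", "cn_mean",
            "call", "punches_agree",
        ],
    )
    conc_rows = []
    for (gene, pat), sub in focus_summary.groupby(["gene", "patient_id"]):
        uniq = sorted(sub["call"].unique())
        conc_rows.append(
            (
                gene, pat, len(sub), ",".join(uniq),
                len(uniq) == 1, len(uniq) == 1 and uniq[0] != "neutral",
            )
        )
    patient_concordance = pd.DataFrame(
        conc_rows,
        columns=[
            "gene", "patient_id", "n_foci", "calls", "concordant",
            "concordant_aberrant",
        ],
    )
    return focus_summary, patient_concordance


def ddct_copy_number(
    ct_target_sample: float,
    ct_control_sample: float,
    ct_target_normal: float,
    ct_control_normal: float,
) -> float:
    """Copy number from qPCR cycle thresholds by the delta-delta-CT method.

    ddCT = (CT_target - CT_control)_sample - (CT_target - CT_control)_normal
    and CN = 2 * 2^(-ddCT), so equal CTs give the diploid CN = 2.
    """
    for ct in (ct_target_sample, ct_control_sample, ct_target_normal,
               ct_control_normal):
        if not np.isfinite(ct):
            raise ValueError("CT values must be finite")
    ddct = (ct_target_sample - ct_control_sample) - (
        ct_target_normal - ct_control_normal
    )
    return float(2.0 * 2.0 ** (-ddct))


def cn_expression_correlation(cn, expr) -> tuple[float, float]:
    """Spearman correlation between one gene's copy number and expression.

    Returns (rho, p) with average ranks for ties and the large-sample
    p-value; (nan, nan) when either vector is constant.
    """
    cn = np.asarray(cn, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if cn.shape != expr.shape or cn.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(cn) == 0 or np.ptp(expr) == 0:
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(cn, expr)
    return float(rho), float(p)
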