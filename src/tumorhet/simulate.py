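"""Synthetic data with the exact statistical structure the analysis assumes.

The generator emulates the multifocal study design: ~11 patients each
contributing 2-3 tumor foci with 3 punches per focus, plus a handful of
adjacent-normal punches.  Per gene g and sample s the latent log2
expression is

    x_gs = mu_g + delta_g * [tumor] + grade effect + a_{g,patient}
           + b_{g,focus} + e_gs,

with a ~ N(0, sigma_P^2), b ~ N(0, sigma_F^2), e ~ N(0, sigma_IT^2), and
observed counts round(2^x * depth_s) for a per-sample depth factor.
Reference genes are generated with near-zero biological variance (a few
deliberately unstable ones exercise the reference-selection step).  The
full latent state is returned as a :class:`TruthRecord` so recovery tests
can compare every estimate to its generating value.

Probe-count (copy-number) and qPCR cycle-threshold tables are generated
from integer copy-number states that can be shared across a patient's foci
(clonal events) or private to one focus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .copynumber import ProbeCountMatrix
from .io import CountMatrix, SampleTable

__all__ = [
    "SimConfig",
    "CNEvent",
    "TruthRecord",
    "simulate_expression",
    "simulate_cnv",
    "simulate_qpcr",
]


@dataclass
class CNEvent:
    """A planted copy-number event.

    ``focus`` of None plants the event in every focus of the patient
    (clonal); a focus label restricts it to that focus (private).
    """

    patient: str
    gene: str
    cn: int
    focus: Optional[str] = None


def _default_cn_events() -> list["CNEvent"]:
    # one high clonal amplification, one low clonal gain, one private gain
    return [
        CNEvent(patient="P11", gene="CNG01", cn=8),
        CNEvent(patient="P01", gene="CNG01", cn=3),
        CNEvent(patient="P08", gene="CNG02", cn=4, focus="F1"),
    ]


@dataclass
class SimConfig:
    """Study-design and distributional settings for the generator.

    Defaults mirror the emulated study: 11 patients, 2-3 foci each, 3
    punches per focus, 7 adjacent-normal punches, a 730-gene endogenous
    panel with 40 candidate reference genes (4 of them unstable), and a
    ~60% fraction of genes with real between-foci variability.
    """

    seed: int
    n_patients: int = 11
    foci_per_patient: tuple[int, ...] = (3, 2, 2, 2, 2, 2, 2, 2, 2, 3, 2)
    punches_per_focus: int = 3
    n_normals: int = 7
    n_genes: int = 730
    n_reference: int = 40
    n_reference_unstable: int = 4
    # endogenous-gene effect distributions (log2 scale)
    mu_range: tuple[float, float] = (5.0, 11.0)
    frac_het: float = 0.6
    sigma_P_range: tuple[float, float] = (0.2, 0.8)
    sigma_F_het_range: tuple[float, float] = (0.5, 1.2)
    sigma_F_null: float = 0.0
    sigma_IT_range: tuple[float, float] = (0.3, 0.6)
    frac_de: float = 0.3
    delta_range: tuple[float, float] = (0.5, 2.5)  # |tumor shift|, sign random
    grade_sd: float = 0.2
    depth_log2_sd: float = 0.4
    ref_sigma_IT: float = 0.05
    ref_unstable_sigma: float = 0.6
    poisson_layer: bool = False
    # explicit per-gene parameters override the sampling ranges when given
    sigma_triples: Optional[np.ndarray] = None  # (n_genes, 3)
    deltas: Optional[np.ndarray] = None  # (n_genes,)
    # copy-number settings
    n_cn_genes: int = 80
    n_invariant_probes: int = 54
    probes_per_gene: tuple[int, int] = (2, 3)
    cn_noise_sd: float = 0.1  # multiplicative lognormal, log scale
    cn_events: list[CNEvent] = field(default_factory=_default_cn_events)
    n_cn_normals: int = 16
    qpcr_ct_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if len(self.foci_per_patient) != self.n_patients:
            raise ValueError(
                "foci_per_patient must list one value per patient"
            )
        if any(f < 1 for f in self.foci_per_patient):
            raise ValueError("every patient needs at least one focus")
        if not 1 <= self.punches_per_focus <= 3:
            raise ValueError("punches_per_focus must be 1-3")
        if self.n_reference_unstable > self.n_reference:
            raise ValueError("more unstable than total reference genes")


@dataclass
class TruthRecord:
    """Every latent quantity sampled by the generator."""

    mu: pd.Series
    delta: pd.Series
    sigma: pd.DataFrame  # gene x (sigma_P, sigma_F, sigma_IT)
    grade_effect: pd.Series
    patient_effects: pd.DataFrame  # gene x patient
    focus_effects: pd.DataFrame  # gene x focus (patient::focus)
    depth: pd.Series  # per sample
    grades: pd.Series  # per focus
    cn_states: Optional[pd.DataFrame] = None  # gene x sample integer CN
    probe_base: Optional[pd.Series] = None
    cn_normal_samples: Optional[list] = None


def _design(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_patients):
        pat = f"P{i + 1:02d}"
        nf = cfg.foci_per_patient[i]
        # focus labels are size-ordered: F1 is the largest lesion
        sizes = np.sort(np.round(rng.uniform(0.5, 6.0, size=nf), 1))[::-1]
        sizes = sizes - 0.01 * np.arange(nf)  # break exact ties
        for j in range(nf):
            foc = f"F{j + 1}"
            size = float(sizes[j])
            grade = int(rng.integers(1, 3))
            for k in range(cfg.punches_per_focus):
                rows.append(
                    {
                        "sample_id": f"{pat}_{foc}_c{k + 1}",
                        "patient_id": pat,
                        "focus_id": foc,
                        "punch_id": f"c{k + 1}",
                        "tissue": "tumor",
                        "grade": grade,
                        "focus_size_cm": size,
                    }
                )
    for i in range(cfg.n_normals):
        pat = f"P{(i % cfg.n_patients) + 1:02d}"
        rows.append(
            {
                "sample_id": f"{pat}_N{i // cfg.n_patients + 1}",
                "patient_id": pat,
                "focus_id": "",
                "punch_id": "N1",
                "tissue": "normal",
                "grade": "",
                "focus_size_cm": np.nan,
            }
        )
    return pd.DataFrame(rows)


def simulate_expression(
    cfg: SimConfig,
) -> tuple[CountMatrix, SampleTable, TruthRecord]:
    """Generate a count matrix, annotations and the latent truth."""
    rng = np.random.default_rng(cfg.seed)
    design = _design(cfg, rng)
    st = SampleTable(design)
    meta = st.data
    n_samples = len(meta)
    is_tumor = (meta["tissue"] == "tumor").to_numpy()
    patients = meta["patient_id"].to_numpy()
    focus_keys = np.array(
        [
            f"{p}::{f}" if f else f"{p}::__none__{s}"
            for p, f, s in zip(
                meta["patient_id"], meta["focus_id"], meta["sample_id"]
            )
        ]
    )
    tumor_focus_levels = sorted(set(focus_keys[is_tumor]))
    patient_levels = sorted(set(patients))

    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    refs = [f"REF{i + 1:02d}" for i in range(cfg.n_reference)]
    all_genes = genes + refs

    mu_endo = rng.uniform(*cfg.mu_range, size=cfg.n_genes)
    if cfg.sigma_triples is not None:
        sig = np.asarray(cfg.sigma_triples, dtype=float)
        if sig.shape != (cfg.n_genes, 3):
            raise ValueError("sigma_triples must be (n_genes, 3)")
    else:
        het = rng.random(cfg.n_genes) < cfg.frac_het
        sP = rng.uniform(*cfg.sigma_P_range, size=cfg.n_genes)
        sF = np.where(
            het,
            rng.uniform(*cfg.sigma_F_het_range, size=cfg.n_genes),
            cfg.sigma_F_null,
        )
        sIT = rng.uniform(*cfg.sigma_IT_range, size=cfg.n_genes)
        sig = np.column_stack([sP, sF, sIT])
    if cfg.deltas is not None:
        delta = np.asarray(cfg.deltas, dtype=float)
        if delta.shape != (cfg.n_genes,):
            raise ValueError("deltas must have length n_genes")
    else:
        de = rng.random(cfg.n_genes) < cfg.frac_de
        mag = rng.uniform(*cfg.delta_range, size=cfg.n_genes)
        sign = rng.choice([-1.0, 1.0], size=cfg.n_genes)
        delta = np.where(de, sign * mag, 0.0)
    grade_eff = rng.normal(0.0, cfg.grade_sd, size=cfg.n_genes)

    # reference genes: high stable expression, tiny residual noise; the
    # last n_reference_unstable get inflated variance so geNorm can drop them
    mu_ref = rng.uniform(9.0, 13.0, size=cfg.n_reference)
    sig_ref = np.zeros((cfg.n_reference, 3))
    sig_ref[:, 2] = cfg.ref_sigma_IT
    if cfg.n_reference_unstable:
        sig_ref[-cfg.n_reference_unstable:, 2] = cfg.ref_unstable_sigma

    mu = np.concatenate([mu_endo, mu_ref])
    sig_all = np.vstack([sig, sig_ref])
    delta_all = np.concatenate([delta, np.zeros(cfg.n_reference)])
    grade_all = np.concatenate([grade_eff, np.zeros(cfg.n_reference)])

    n_all = len(all_genes)
    a = rng.normal(size=(n_all, len(patient_levels))) * sig_all[:, [0]]
    b = rng.normal(size=(n_all, len(tumor_focus_levels))) * sig_all[:, [1]]
    e = rng.normal(size=(n_all, n_samples)) * sig_all[:, [2]]

    pat_idx = {p: i for i, p in enumerate(patient_levels)}
    foc_idx = {f: i for i, f in enumerate(tumor_focus_levels)}
    grades = meta["grade"].to_numpy()
    grade_num = np.array(
        [float(g) - 1.0 if t and g != "" else 0.0
         for g, t in zip(grades.astype(str), is_tumor)]
    )

    x = np.empty((n_all, n_samples))
    for s in range(n_samples):
        x[:, s] = (
            mu
            + delta_all * (1.0 if is_tumor[s] else 0.0)
            + grade_all * grade_num[s]
            + a[:, pat_idx[patients[s]]]
            + (b[:, foc_idx[focus_keys[s]]] if is_tumor[s] else 0.0)
            + e[:, s]
        )

    depth = 2.0 ** rng.normal(0.0, cfg.depth_log2_sd, size=n_samples)
    lam = (2.0**x) * depth[None, :]
    if cfg.poisson_layer:
        counts = rng.poisson(lam)
    else:
        counts = np.rint(lam).astype(np.int64)
    cm = CountMatrix(
        pd.DataFrame(counts, index=all_genes, columns=meta["sample_id"]),
        pd.Series(
            ["endogenous"] * cfg.n_genes + ["reference"] * cfg.n_reference,
            index=all_genes,
        ),
    )
    truth = TruthRecord(
        mu=pd.Series(mu, index=all_genes),
        delta=pd.Series(delta_all, index=all_genes),
        sigma=pd.DataFrame(
            sig_all, index=all_genes, columns=["sigma_P", "sigma_F", "sigma_IT"]
        ),
        grade_effect=pd.Series(grade_all, index=all_genes),
        patient_effects=pd.DataFrame(
            a, index=all_genes, columns=patient_levels
        ),
        focus_effects=pd.DataFrame(
            b, index=all_genes, columns=tumor_focus_levels
        ),
        depth=pd.Series(depth, index=meta["sample_id"]),
        grades=pd.Series(
            {
                f"{p}::{f}": g
                for p, f, g in meta[is_tumor][
                    ["patient_id", "focus_id", "grade"]
                ].drop_duplicates().itertuples(index=False)
            }
        ),
    )
    return cm, st, truth


def simulate_cnv(
    cfg: SimConfig,
) -> tuple[ProbeCountMatrix, SampleTable, TruthRecord]:
    """Generate a probe-count matrix with planted integer copy-number states.

    The tumor design matches :func:`simulate_expression`; an additional
    ``n_cn_normals`` adjacent-normal punches form the diploid reference.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    design = _design(cfg, rng)
    tum = design[design["tissue"] == "tumor"].copy()
    normals = pd.DataFrame(
        {
            "sample_id": [f"NREF{i + 1:02d}" for i in range(cfg.n_cn_normals)],
            "patient_id": [
                f"NP{i + 1:02d}" for i in range(cfg.n_cn_normals)
            ],
            "focus_id": "",
            "punch_id": "N1",
            "tissue": "normal",
            "grade": "",
            "focus_size_cm": np.nan,
        }
    )
    design = pd.concat([tum, normals], ignore_index=True)
    st = SampleTable(design)
    meta = st.data

    genes = [f"CNG{i + 1:02d}" for i in range(cfg.n_cn_genes)]
    probe_rows, probe_gene, probe_class = [], {}, {}
    for g in genes:
        k = int(rng.integers(cfg.probes_per_gene[0], cfg.probes_per_gene[1] + 1))
        for j in range(k):
            pid = f"{g}_p{j + 1}"
            probe_rows.append(pid)
            probe_gene[pid] = g
            probe_class[pid] = "target"
    for i in range(cfg.n_invariant_probes):
        pid = f"INV{i + 1:02d}"
        probe_rows.append(pid)
        probe_class[pid] = "invariant"

    # integer CN states: 2 everywhere, overwritten by planted events
    cn = pd.DataFrame(
        2, index=genes, columns=meta["sample_id"], dtype=int
    )
    for ev in cfg.cn_events:
        if ev.gene not in cn.index:
            continue
        sel = meta["patient_id"] == ev.patient
        if ev.focus is not None:
            sel &= meta["focus_id"] == ev.focus
        sel &= meta["tissue"] == "tumor"
        cn.loc[ev.gene, meta.loc[sel, "sample_id"]] = ev.cn

    base = pd.Series(
        rng.uniform(200.0, 1500.0, size=len(probe_rows)), index=probe_rows
    )
    depth = 2.0 ** rng.normal(0.0, cfg.depth_log2_sd, size=len(meta))
    counts = np.empty((len(probe_rows), len(meta)))
    for i, pid in enumerate(probe_rows):
        if probe_class[pid] == "invariant":
            level = np.full(len(meta), base[pid])
        else:
            level = base[pid] * cn.loc[probe_gene[pid]].to_numpy() / 2.0
        noise = np.exp(rng.normal(0.0, cfg.cn_noise_sd, size=len(meta)))
        counts[i] = level * depth * noise
    pm = ProbeCountMatrix(
        pd.DataFrame(counts, index=probe_rows, columns=meta["sample_id"]),
        pd.Series(probe_gene),
        pd.Series(probe_class),
    )
    truth = TruthRecord(
        mu=pd.Series(dtype=float),
        delta=pd.Series(dtype=float),
        sigma=pd.DataFrame(),
        grade_effect=pd.Series(dtype=float),
        patient_effects=pd.DataFrame(),
        focus_effects=pd.DataFrame(),
        depth=pd.Series(depth, index=meta["sample_id"]),
        grades=pd.Series(dtype=object),
        cn_states=cn,
        probe_base=base,
        cn_normal_samples=list(normals["sample_id"]),
    )
    return pm, st, truth


def simulate_qpcr(
    cfg: SimConfig,
    truth: TruthRecord,
    gene: str = "CNG01",
    c0: float = 26.0,
    c_control: float = 24.0,
) -> pd.DataFrame:
    """qPCR cycle thresholds consistent with the planted CN states.

    ct_target = c0 - log2(CN/2) + noise, ct_control = c_control + noise,
    so the delta-delta-CT estimator recovers CN exactly in the noiseless
    case.  Returns one row per sample with its patient and tissue.
    """
    if truth.cn_states is None:
        raise ValueError("truth record has no CN states; run simulate_cnv")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    cn = truth.cn_states.loc[gene]
    rows = []
    for sample, state in cn.items():
        is_ref = sample in set(truth.cn_normal_samples or [])
        rows.append(
            {
                "sample_id": sample,
                "tissue": "normal" if is_ref else "tumor",
                "target_ct": c0
                - np.log2(state / 2.0)
                + rng.normal(0.0, cfg.qpcr_ct_sd),
                "control_ct": c_control + rng.normal(0.0, cfg.qpcr_ct_sd),
                "true_cn": int(state),
            }
        )
    return pd.DataFrame(rows)
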