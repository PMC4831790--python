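"""End-to-end pipeline runner: normalize -> DE -> heterogeneity -> pathway
-> copy number, with a content-hashed output manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import copynumber as cnmod
from . import diffexpr, heterogeneity, normalization, pathway
from .io import (
    read_annotations,
    read_counts,
    read_panel,
    validate_design,
    write_table,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("tumorhet")


@dataclass
class RunConfig:
    """Configuration for one pipeline run (mirrors the CLI flags)."""

    counts_path: str
    annotations_path: str
    output_dir: str
    panel_path: Optional[str] = None
    probe_counts_path: Optional[str] = None
    counts_dialect: str = "wide_csv"
    n_reference_keep: int = 36
    pseudocount: float = 1.0
    genorm_mode: str = "iterative"
    lrt_convention: str = "chisq1"
    de_include_grade: bool = False
    fc_up: float = 2.0
    fc_down: float = 0.5
    q_max: float = 0.05
    del_thresh: float = 1.5
    amp_thresh: float = 3.0
    cn_normal_ref: list[str] = field(default_factory=list)
    stages: tuple[str, ...] = ("normalize", "de", "het", "pathway", "cnv")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        for label, p in [
            ("counts", self.counts_path),
            ("annotations", self.annotations_path),
            ("panel", self.panel_path),
            ("probe_counts", self.probe_counts_path),
        ]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        if "pathway" in self.stages and self.panel_path is None:
            raise ValueError("pathway stage requires panel_path")
        if "cnv" in self.stages and self.probe_counts_path is None:
            raise ValueError("cnv stage requires probe_counts_path")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages in order; returns the manifest dict.

    Every output file is recorded with a sha256 content hash so repeated
    runs of deterministic stages can be verified byte-for-byte.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df, name):
        path = out / name
        write_table(df, path)
        written.append(path)
        log.info("[%s] wrote %s", stage, path.name)
        return path

    # config echo
    cfg_path = out / "run_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in vars(cfg).items()},
            fh,
        )
    written.append(cfg_path)

    stage = "load"
    cm = read_counts(cfg.counts_path, cfg.counts_dialect)
    st = read_annotations(cfg.annotations_path)
    summary = validate_design(cm, st)
    log.info(
        "[load] %d patients, %d foci, %d tumor + %d normal samples",
        summary.n_patients, summary.n_foci,
        summary.n_tumor_samples, summary.n_normal_samples,
    )

    logm = None
    de = None
    if "normalize" in cfg.stages:
        stage = "normalize"
        refs = cm.reference_genes
        ranking = normalization.genorm_stability(
            cm.counts.loc[refs].astype(float).clip(lower=cfg.pseudocount),
            mode=cfg.genorm_mode,
        )
        keep = normalization.select_reference_genes(
            ranking, min(cfg.n_reference_keep, len(refs))
        )
        normed = normalization.normalize(cm, keep, cfg.pseudocount)
        logm = normalization.log_transform(normed, cfg.pseudocount)
        rank_df = (
            ranking.iterative_m.rename("M")
            .reset_index()
            .rename(columns={"index": "gene"})
        )
        rank_df["kept"] = rank_df["gene"].isin(keep)
        emit(rank_df, "reference_stability.tsv")
        emit(
            logm.values.reset_index(names="gene"),
            "log2_normalized.tsv",
        )

    if "de" in cfg.stages:
        stage = "de"
        if logm is None:
            raise RuntimeError("de stage requires the normalize stage")
        de = diffexpr.differential_expression(
            logm, st, include_grade=cfg.de_include_grade
        )
        emit(de, "differential_expression.tsv")
        emit(
            diffexpr.filter_de(de, cfg.fc_up, cfg.fc_down, cfg.q_max),
            "differential_expression_filtered.tsv",
        )

    if "het" in cfg.stages:
        stage = "het"
        if logm is None:
            raise RuntimeError("het stage requires the normalize stage")
        endo = [g for g in logm.genes if g in set(cm.endogenous_genes)]
        het = heterogeneity.heterogeneity_analysis(
            type(logm)(logm.values.loc[endo], is_log2=True),
            st,
            lrt_convention=cfg.lrt_convention,
        )
        emit(het, "heterogeneity.tsv")

    if "pathway" in cfg.stages:
        stage = "pathway"
        if logm is None or de is None:
            raise RuntimeError("pathway stage requires normalize and de")
        panel = read_panel(cfg.panel_path)
        baseline = list(st.normal["sample_id"])
        scores = {}
        for name, genes in sorted(panel.pathways.items()):
            scores[name] = pathway.pathway_score(
                logm, genes, baseline, name=name
            )
        pw_p = pathway.pathway_differential(scores, st, "tumor_vs_normal")
        table = pathway.significance_plot_table(pw_p, de, panel.pathways)
        emit(table, "pathway_significance.tsv")
        score_frames = [
            ps.scores.rename(name) for name, ps in sorted(scores.items())
        ]
        import pandas as pd

        emit(
            pd.concat(score_frames, axis=1).reset_index(names="sample_id"),
            "pathway_scores.tsv",
        )

    if "cnv" in cfg.stages:
        stage = "cnv"
        pm = cnmod.read_probe_counts(cfg.probe_counts_path)
        # default reference: declared normals, else any probe-matrix sample
        # that is not a tumor punch (the CNV run has its own normal set)
        normal_ref = cfg.cn_normal_ref or [
            s for s in st.normal["sample_id"] if s in set(pm.samples)
        ] or [
            s for s in pm.samples
            if s not in set(st.tumor["sample_id"])
        ]
        cn = cnmod.estimate_copy_number(pm, normal_ref)
        calls = cnmod.call_copy_state(cn, cfg.del_thresh, cfg.amp_thresh)
        emit(cn.cn.reset_index(names="gene"), "copy_number.tsv")
        emit(calls.reset_index(names="gene"), "copy_number_calls.tsv")
        foc, conc = cnmod.focus_consistency(
            cn, st, cfg.del_thresh, cfg.amp_thresh
        )
        emit(foc, "cn_focus_summary.tsv")
        emit(conc, "cn_patient_concordance.tsv")

    manifest = {
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in written
        },
        "stages": list(cfg.stages),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
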