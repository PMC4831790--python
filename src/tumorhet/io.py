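"""Data containers and readers/writers for panel count data and sample designs.

The package works with three tabular inputs:

* a wide gene x sample count matrix (first column the gene identifier, a
  ``gene_class`` column, then one column per sample),
* a sample annotation table describing the nested sampling design
  (patient -> focus -> punch, plus tissue and grade),
* a pathway membership file (two-column TSV: pathway, gene).

Raw counts are integer-valued and live in :class:`CountMatrix`; normalized
and log-scale values live in the real-valued :class:`ExpressionMatrix` so
that raw counts cannot silently be reused downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "SampleTable",
    "PanelDefinition",
    "DesignSummary",
    "read_counts",
    "read_annotations",
    "read_panel",
    "validate_design",
    "write_counts",
    "write_table",
    "read_table",
]

GENE_CLASSES = ("endogenous", "reference", "invariant_control")

#: mapping from NanoString-style RCC export CodeClass labels to panel classes
_RCC_CLASS_MAP = {
    "endogenous": "endogenous",
    "housekeeping": "reference",
    "reference": "reference",
    "invariant": "invariant_control",
}


class DesignError(ValueError):
    """Raised when inputs violate a design or panel invariant."""


def _check_unique(values, what: str) -> None:
    s = pd.Series(list(values))
    dup = s[s.duplicated()]
    if len(dup):
        raise DesignError(f"duplicate {what}: {sorted(set(dup))}")


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample counts with per-gene panel classes.

    Parameters
    ----------
    counts : pandas.DataFrame
        Genes in rows, samples in columns; integer dtype enforced.
    gene_class : pandas.Series
        One of ``endogenous``, ``reference``, ``invariant_control`` per gene,
        indexed like ``counts``.
    """

    counts: pd.DataFrame
    gene_class: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.counts.index = self.counts.index.astype(str).str.strip()
        self.counts.columns = self.counts.columns.astype(str).str.strip()
        self.counts.index.name = None
        self.counts.columns.name = None
        _check_unique(self.counts.index, "gene identifiers")
        _check_unique(self.counts.columns, "sample identifiers")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DesignError("counts must be numeric")
        if np.isnan(arr.astype(float)).any():
            i, j = np.argwhere(np.isnan(arr.astype(float)))[0]
            raise DesignError(
                f"non-numeric count at gene {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise DesignError(
                f"negative count at gene {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        gc = self.gene_class.copy()
        gc.index = gc.index.astype(str).str.strip()
        gc = gc.astype(str).str.strip()
        missing = set(self.counts.index) - set(gc.index)
        if missing:
            raise DesignError(f"genes without a class: {sorted(missing)}")
        gc = gc.reindex(self.counts.index)
        gc.index.name = None
        gc.name = None
        bad = gc[~gc.isin(GENE_CLASSES)]
        if len(bad):
            raise DesignError(
                f"unknown gene class {bad.iloc[0]!r} for gene {bad.index[0]!r}"
            )
        self.gene_class = gc

    # -- convenience views -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def genes_of_class(self, cls: str) -> list[str]:
        if cls not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {cls!r}")
        return list(self.gene_class.index[self.gene_class == cls])

    @property
    def endogenous_genes(self) -> list[str]:
        return self.genes_of_class("endogenous")

    @property
    def reference_genes(self) -> list[str]:
        return self.genes_of_class("reference")


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample expression (normalized and/or log2)."""

    values: pd.DataFrame
    is_log2: bool = False

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "gene identifiers")
        _check_unique(self.values.columns, "sample identifiers")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


_TISSUE_SYNONYMS = {
    "tumor": "tumor",
    "tumour": "tumor",
    "t": "tumor",
    "normal": "normal",
    "adjacent normal": "normal",
    "adjacent_normal": "normal",
    "n": "normal",
}

_REQUIRED_ANNOT_COLS = (
    "sample_id",
    "patient_id",
    "focus_id",
    "punch_id",
    "tissue",
    "grade",
)


@dataclass
class SampleTable:
    """Per-sample design metadata for the nested patient/focus/punch layout.

    Tumor samples must carry a focus identifier; adjacent-normal samples
    leave it empty.  Each focus holds one to three punches.
    """

    data: pd.DataFrame
    max_punches_per_focus: int = 3

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in _REQUIRED_ANNOT_COLS if c not in df.columns]
        if missing:
            raise DesignError(f"annotation table missing columns: {missing}")
        for c in ("sample_id", "patient_id", "focus_id", "punch_id"):
            df[c] = df[c].fillna("").astype(str).str.strip()
        _check_unique(df["sample_id"], "sample identifiers")
        tissue = df["tissue"].astype(str).str.strip().str.lower()
        unknown = tissue[~tissue.isin(_TISSUE_SYNONYMS)]
        if len(unknown):
            raise DesignError(f"unknown tissue label {unknown.iloc[0]!r}")
        df["tissue"] = tissue.map(_TISSUE_SYNONYMS)
        no_focus = df[(df["tissue"] == "tumor") & (df["focus_id"] == "")]
        if len(no_focus):
            raise DesignError(
                "tumor samples without focus_id: "
                f"{sorted(no_focus['sample_id'])}"
            )
        tum = df[df["tissue"] == "tumor"]
        trip = tum[["patient_id", "focus_id", "punch_id"]]
        if trip.duplicated().any():
            dup = trip[trip.duplicated()].iloc[0]
            raise DesignError(
                f"duplicate (patient, focus, punch) triple: {tuple(dup)}"
            )
        sizes = tum.groupby(["patient_id", "focus_id"]).size()
        too_big = sizes[sizes > self.max_punches_per_focus]
        if len(too_big):
            p, f = too_big.index[0]
            raise DesignError(
                f"focus {f!r} of patient {p!r} has {too_big.iloc[0]} punches "
                f"(max {self.max_punches_per_focus})"
            )
        if "focus_size_cm" in df.columns:
            fs = pd.to_numeric(df["focus_size_cm"], errors="coerce")
            if (fs.dropna() <= 0).any():
                raise DesignError("focus_size_cm must be positive where given")
            df["focus_size_cm"] = fs
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def subset(self, sample_ids) -> "SampleTable":
        keep = self.data[self.data["sample_id"].isin(set(sample_ids))]
        return SampleTable(keep, self.max_punches_per_focus)

    @property
    def tumor(self) -> pd.DataFrame:
        return self.data[self.data["tissue"] == "tumor"]

    @property
    def normal(self) -> pd.DataFrame:
        return self.data[self.data["tissue"] == "normal"]


@dataclass
class PanelDefinition:
    """Pathway membership and reference-gene candidates for one panel."""

    pathways: dict[str, set[str]]
    reference_candidates: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.pathways) < 1:
            raise DesignError("panel must define at least one pathway")
        self.pathways = {
            str(k): {str(g).strip() for g in v} for k, v in self.pathways.items()
        }

    def missing_genes(self, cm: CountMatrix) -> dict[str, set[str]]:
        present = set(cm.genes)
        return {
            p: genes - present
            for p, genes in self.pathways.items()
            if genes - present
        }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_counts(path, dialect: str = "wide_csv") -> CountMatrix:
    """Read a gene x sample count matrix.

    ``wide_csv``: first column gene id, a ``gene_class`` column, then one
    column per sample.  ``rcc_export``: nSolver-style CSV export with
    ``CodeClass``, ``Name`` (and optionally ``Accession``) columns followed
    by sample columns; positive/negative control probes are dropped.
    """
    if dialect == "wide_csv":
        df = pd.read_csv(path, index_col=0)
        if "gene_class" not in df.columns:
            raise DesignError("wide_csv requires a 'gene_class' column")
        gene_class = df["gene_class"]
        counts = df.drop(columns=["gene_class"])
    elif dialect == "rcc_export":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "codeclass" not in cols or "name" not in cols:
            raise DesignError("rcc_export requires CodeClass and Name columns")
        cc = df[cols["codeclass"]].astype(str).str.strip().str.lower()
        keep = cc.isin(_RCC_CLASS_MAP)
        dropped = sorted(set(cc[~keep]))
        if dropped:
            warnings.warn(
                f"dropping control code classes: {dropped}", stacklevel=2
            )
        df = df[keep]
        gene_class = cc[keep].map(_RCC_CLASS_MAP)
        gene_class.index = df[cols["name"]].astype(str).str.strip()
        drop_cols = [cols["codeclass"], cols["name"]]
        if "accession" in cols:
            drop_cols.append(cols["accession"])
        counts = df.drop(columns=drop_cols)
        counts.index = gene_class.index
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return CountMatrix(counts, gene_class)


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.insert(0, "gene_class", cm.gene_class)
    out.to_csv(path, index_label="gene")


def read_annotations(path) -> SampleTable:
    """Read the six-column sample annotation CSV into a :class:`SampleTable`."""
    df = pd.read_csv(path, dtype=str)
    return SampleTable(df)


def write_annotations(st: SampleTable, path) -> None:
    st.data.to_csv(path, index=False)


def read_panel(path) -> PanelDefinition:
    """Read a two-column TSV (pathway, gene) into a :class:`PanelDefinition`."""
    df = pd.read_csv(path, sep="\t", header=None, names=["pathway", "gene"])
    pathways: dict[str, set[str]] = {}
    for p, sub in df.groupby("pathway"):
        pathways[str(p)] = set(sub["gene"].astype(str))
    return PanelDefinition(pathways)


def write_table(df: pd.DataFrame, path, float_precision: int = 6) -> None:
    """Write a results table as TSV with fixed significant-digit precision."""
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# design validation
# ---------------------------------------------------------------------------

@dataclass
class DesignSummary:
    """Counts describing the nested design of one dataset."""

    n_patients: int
    n_foci: int
    n_tumor_samples: int
    n_normal_samples: int
    foci_per_patient: dict[str, int]
    punches_per_focus: dict[tuple[str, str], int]
    single_focus_patients: list[str]


def validate_design(cm: CountMatrix, st: SampleTable) -> DesignSummary:
    """Cross-check a count matrix against its annotation table.

    Every sample must appear in both inputs.  Patients with fewer than two
    foci are listed (they cannot inform between-foci variance on their own
    but are retained in model fits).
    """
    cm_samples = set(cm.samples)
    st_samples = set(st.sample_ids)
    if not st_samples:
        raise DesignError("annotation table is empty")
    only_cm = sorted(cm_samples - st_samples)
    only_st = sorted(st_samples - cm_samples)
    if only_cm or only_st:
        msgs = []
        if only_cm:
            msgs.append(f"samples only in counts: {only_cm}")
        if only_st:
            msgs.append(f"samples only in annotations: {only_st}")
        raise DesignError("; ".join(msgs))
    tum = st.tumor
    foci = tum.groupby("patient_id")["focus_id"].nunique()
    punches = tum.groupby(["patient_id", "focus_id"]).size()
    return DesignSummary(
        n_patients=st.data["patient_id"].nunique(),
        n_foci=int(foci.sum()),
        n_tumor_samples=len(tum),
        n_normal_samples=len(st.normal),
        foci_per_patient={str(k): int(v) for k, v in foci.items()},
        punches_per_focus={
            (str(p), str(f)): int(v) for (p, f), v in punches.items()
        },
        single_focus_patients=sorted(foci.index[foci < 2]),
    )
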