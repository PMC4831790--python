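import numpy as np
import pandas as pd
import pytest

import tumorhet as th


@pytest.fixture(scope="session")
def small_sim():
    """Small study-design simulation shared across tests (20 genes)."""
    cfg = th.SimConfig(seed=101, n_genes=20)
    cm, st, truth = th.simulate_expression(cfg)
    return cfg, cm, st, truth


@pytest.fixture(scope="session")
def study_design():
    """Tumor-only design frame at the study scale (11 patients, 2-3 foci,
    3 punches) for direct model construction."""
    cfg = th.SimConfig(seed=102, n_genes=1)
    _, st, _ = th.simulate_expression(cfg)
    tum = st.tumor.set_index("sample_id")
    return tum


@pytest.fixture(scope="session")
def small_log2(small_sim):
    """Normalized log2 matrix for the shared simulation."""
    _, cm, st, _ = small_sim
    ranking = th.genorm_stability(cm.counts.loc[cm.reference_genes].astype(float))
    keep = th.select_reference_genes(ranking, 36)
    return th.log_transform(th.normalize(cm, keep), 1.0), st


def toy_sample_table(n_patients=3, n_foci=2, n_punch=3, n_normals=2):
    rows = []
    for i in range(n_patients):
        pat = f"P{i+1}"
        for j in range(n_foci):
            for k in range(n_punch):
                rows.append(
                    dict(
                        sample_id=f"{pat}F{j+1}c{k+1}", patient_id=pat,
                        focus_id=f"F{j+1}", punch_id=f"c{k+1}",
                        tissue="tumor", grade=1 + (j % 2),
                    )
                )
    for i in range(n_normals):
        rows.append(
            dict(
                sample_id=f"P{i+1}N", patient_id=f"P{i+1}", focus_id="",
                punch_id="N1", tissue="normal", grade="",
            )
        )
    return th.SampleTable(pd.DataFrame(rows))


@pytest.fixture
def toy_table():
    return toy_sample_table()


def make_count_matrix(rng, n_genes=5, n_samples=4, classes=None):
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    counts = pd.DataFrame(
        rng.integers(10, 1000, size=(n_genes, n_samples)),
        index=genes, columns=samples,
    )
    if classes is None:
        classes = ["endogenous"] * n_genes
    return th.CountMatrix(counts, pd.Series(classes, index=genes))
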