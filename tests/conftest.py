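import numpy as np
import pandas as pd
import pytest

from refstab.screening import ExpressionDataset
from refstab.stability import CqPanel


def make_panel(cq_array, groups=None, gene_ids=None, efficiency=2.0) -> CqPanel:
    cq_array = np.asarray(cq_array, dtype=float)
    m, n = cq_array.shape
    gene_ids = gene_ids or [f"G{i+1}" for i in range(m)]
    sample_ids = [f"s{j+1}" for j in range(n)]
    if groups is None:
        groups = ["A"] * n
    cq = pd.DataFrame(cq_array, index=gene_ids, columns=sample_ids)
    return CqPanel(cq=cq, groups=pd.Series(list(groups), index=sample_ids), efficiency=efficiency)


def make_dataset(values, tissue="CL", platform="rnaseq", dataset_id="ds1",
                 health=None, condition=None) -> ExpressionDataset:
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    genes = [f"G{i+1}" for i in range(m)]
    samples = [f"s{j+1}" for j in range(n)]
    labels = pd.DataFrame(
        {
            "condition": condition or ["c"] * n,
            "health": health or ["healthy"] * n,
        },
        index=samples,
    )
    return ExpressionDataset(
        dataset_id=dataset_id,
        tissue=tissue,
        platform=platform,
        abundances=pd.DataFrame(values, index=genes, columns=samples),
        sample_labels=labels,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20201112)


@pytest.fixture
def random_small_panels(rng):
    """Random Cq panels up to 5 genes x 6 samples for oracle cross-checks."""
    panels = []
    for m in (3, 4, 5):
        for n in (4, 6):
            cq = rng.normal(25.0, 2.0, size=(m, n))
            panels.append(make_panel(cq, groups=["A"] * (n // 2) + ["B"] * (n - n // 2)))
    return panels
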