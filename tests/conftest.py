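import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from modrank.io import ExpressionMatrix, GeneModule, ModuleCollection
from modrank.mdi import ReferenceDataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(genes, samples, values) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)
    )


def make_dataset(name, genes, sample_spec, values, states=None) -> ReferenceDataset:
    """sample_spec: list of (sample_id, cell_type); values: genes x samples."""
    sample_ids = [s for s, _ in sample_spec]
    ann = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cell_type": [c for _, c in sample_spec],
        }
    )
    if states is not None:
        ann["state"] = states
    ann = ann.set_index("sample_id", drop=False)
    return ReferenceDataset(name, make_matrix(genes, sample_ids, values), ann)


@pytest.fixture
def tiny_collection() -> ModuleCollection:
    return ModuleCollection(
        (
            GeneModule("T_small", frozenset({"CD3D", "CD3E"}), target_cell="T cell"),
            GeneModule("B_small", frozenset({"CD19", "MS4A1"}), target_cell="B cell"),
        )
    )
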