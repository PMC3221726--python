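import numpy as np
import pandas as pd
import pytest

from stepclf.io import ClinicalSchema, ClinicalTable
from stepclf.synthetic import GeneratorConfig, SubgroupSpec, generate


@pytest.fixture
def toy_blobs():
    """Two well-separated Gaussian clusters: any sane classifier is perfect."""
    rng = np.random.default_rng(0)
    n = 40
    X = np.vstack([rng.normal(-4.0, 0.3, size=(n // 2, 3)),
                   rng.normal(4.0, 0.3, size=(n // 2, 3))])
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    perm = rng.permutation(n)
    return X[perm], y[perm]


@pytest.fixture
def mixed_table():
    """A small mixed-type clinical table with missing entries."""
    schema = ClinicalSchema(
        kinds={"age": "continuous", "grade": "ordinal", "er": "binary",
               "subtype": "nominal"},
        ordinal_levels={"grade": ("low", "mid", "high")},
    )
    frame = pd.DataFrame(
        {
            "age": [52.0, np.nan, 61.0, 47.0, 70.0],
            "grade": ["low", "mid", "high", None, "mid"],
            "er": ["pos", "neg", "pos", "pos", None],
            "subtype": ["x", "y", "x", "z", "y"],
        },
        index=pd.Index([f"P{i}" for i in range(1, 6)], name="sample"),
    )
    return ClinicalTable(frame, schema)


@pytest.fixture
def small_dataset():
    """A small paired dataset with a clinically misleading subgroup."""
    cfg = GeneratorConfig(
        n_samples=60, n_molecular=40, n_molecular_signal=10,
        clinical_effect=1.4, molecular_effect=1.0, rho=0.3,
        subgroups=(SubgroupSpec(1, 0.2, "clinical"),), seed=0,
    )
    dataset, annotations = generate(cfg, seed=11)
    return dataset, annotations
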