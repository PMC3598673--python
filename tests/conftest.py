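import numpy as np
import pandas as pd
import pytest

from hqsar.data_model import (
    CompoundRecord,
    DescriptorMatrix,
    DescriptorMeta,
    load_paper_fixture,
)


def make_matrix(values: np.ndarray, n_train: int | None = None,
                names: list[str] | None = None) -> DescriptorMatrix:
    """Build a DescriptorMatrix from a plain array (helper for tests)."""
    n, d = values.shape
    n_train = n if n_train is None else n_train
    names = names or [f"d{j:02d}" for j in range(d)]
    compounds = [
        CompoundRecord(
            id=f"c{i:02d}", name=f"compound {i}",
            role="training" if i < n_train else "test",
        )
        for i in range(n)
    ]
    descriptors = [DescriptorMeta(name=nm, dclass="constitutional") for nm in names]
    return DescriptorMatrix(
        compounds=compounds,
        descriptors=descriptors,
        values=pd.DataFrame(values, index=[c.id for c in compounds], columns=names),
    )


@pytest.fixture(scope="session")
def paper_fixture():
    return load_paper_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
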