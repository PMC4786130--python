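import numpy as np
import pytest

from degpag import ExpressionMatrix, StudyDesign


def build_dataset(values, group, phenotype=None):
    """Wrap raw arrays into aligned (ExpressionMatrix, StudyDesign)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    group = np.asarray(group, dtype=int)
    n = group.size
    if phenotype is None:
        phenotype = np.linspace(0.0, 1.0, n)
    sample_ids = [f"s{i}" for i in range(n)]
    expr = ExpressionMatrix(values, [f"g{i}" for i in range(values.shape[0])], sample_ids)
    design = StudyDesign(
        sample_ids=sample_ids,
        group=group,
        phenotype=np.asarray(phenotype, dtype=float),
        phenotype_name="phenotype",
    )
    return expr, design


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_dataset(rng):
    """8 genes x (3 control + 3 case), pure noise plus one shifted gene."""
    group = np.array([0, 0, 0, 1, 1, 1])
    values = rng.normal(0.0, 1.0, (8, 6))
    values[0, group == 1] += 5.0
    return build_dataset(values, group, phenotype=rng.normal(25.0, 16.0, 6))
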