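import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from crosspath.io import ExpressionStudy, GeneSet, GeneSetCollection

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_study(values: np.ndarray, n1: int, n2: int,
               groups=("normal", "disease")) -> ExpressionStudy:
    """Wrap a raw genes × (n1+n2) array into an ExpressionStudy."""
    n_genes = values.shape[0]
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n1 + n2)]
    labels = pd.Series([groups[0]] * n1 + [groups[1]] * n2, index=samples)
    return ExpressionStudy(
        pd.DataFrame(values, index=genes, columns=samples), labels, tuple(groups))


def make_sets(mapping: dict[str, list[str]]) -> GeneSetCollection:
    col = GeneSetCollection()
    for sid, genes in mapping.items():
        col.add(GeneSet(sid, sid, tuple(genes)))
    return col


@pytest.fixture
def small_study() -> ExpressionStudy:
    rng = np.random.default_rng(11)
    return make_study(rng.normal(8, 1, size=(10, 8)), 4, 4)
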