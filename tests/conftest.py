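import numpy as np
import pandas as pd
import pytest

from fmt_engraft.coda import AbundanceTable, Composition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(counts: np.ndarray, days=None, roles=None,
               subjects=None) -> AbundanceTable:
    """Small abundance table with auto-generated metadata."""
    n_taxa, n_samples = counts.shape
    taxa = [chr(ord("A") + i) for i in range(n_taxa)]
    samples = [f"s{j + 1}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "subject": subjects or ["x"] * n_samples,
            "day": days if days is not None else list(range(n_samples)),
            "role": roles or ["recipient"] * n_samples,
        },
        index=samples,
    )
    return AbundanceTable(pd.DataFrame(counts, index=taxa, columns=samples),
                          meta)


def random_composition(rng, n_parts: int) -> Composition:
    parts = [f"p{i + 1}" for i in range(n_parts)]
    return Composition.close(parts, rng.dirichlet(np.full(n_parts, 2.0)))


@pytest.fixture
def random_table(rng) -> AbundanceTable:
    return make_table(rng.integers(0, 200, size=(20, 10)))
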