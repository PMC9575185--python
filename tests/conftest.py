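import numpy as np
import pandas as pd
import pytest

import dtpescape as d


@pytest.fixture(scope="session")
def small_genome():
    return d.gen_genome(2, 50_000_000, 2)


@pytest.fixture(scope="session")
def rna_fixture():
    """Standard small annotation + abundance truth shared across tests."""
    from dtpescape.benchmarks import standard_rna_fixture

    return standard_rna_fixture(seed=0)


@pytest.fixture(scope="session")
def degraded_reads(rna_fixture):
    ann, truth = rna_fixture
    return d.gen_rnaseq_reads(
        ann, truth, degradation_rate=0.01, directional=True, n_reads=60_000, seed=11
    )


def make_profile(grid, values_by_cell):
    """Build a profile frame over a grid from {cell: {window_index: value}}."""
    cells = list(values_by_cell)
    prof = pd.DataFrame(0.0, index=cells, columns=range(len(grid)))
    for cell, vals in values_by_cell.items():
        for w, v in vals.items():
            prof.loc[cell, w] = v
    return prof


@pytest.fixture
def rng():
    return np.random.default_rng(0)
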