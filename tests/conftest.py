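import numpy as np
import pandas as pd
import pytest

import ribostat as rs


@pytest.fixture(scope="session")
def small_ribo():
    """200 transcripts, 3 vs 3, 10% planted logTER = ln 2."""
    params = rs.RiboSimParams(
        n_transcripts=200, codon_length=60, mean_expression=300.0, seed=11
    )
    rna, rpf, profiles, truth, design = rs.simulate_ribo(params)
    return dict(rna=rna, rpf=rpf, profiles=profiles, truth=truth,
                design=design, params=params)


@pytest.fixture(scope="session")
def small_apa():
    """100 transcripts, 3 vs 3 samples, 10% with delta = 1 proximal shift."""
    params = rs.ApaSimParams(n_transcripts=100, seed=7)
    pas, truth, design = rs.simulate_apa(params)
    return dict(pas=pas, truth=truth, design=design, params=params)


@pytest.fixture
def two_site_pas():
    """One transcript, two sites, (80,20) vs (20,80) across two samples."""
    idx = pd.MultiIndex.from_tuples(
        [("t", "pA1"), ("t", "pA2")], names=["transcript_id", "site_id"]
    )
    counts = pd.DataFrame({"c1": [80.0, 20.0], "c2": [20.0, 80.0]}, index=idx)
    ranks = pd.Series([1, 2], index=idx)
    pas = rs.PasCountTable(counts, ranks, rank_source="manual")
    design = rs.DesignMatrix(
        pd.DataFrame({"condition": [0.0, 1.0]}, index=["c1", "c2"])
    )
    return pas, design


def make_count_matrix(arr, samples=None, read_type="RNA"):
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    idx = [f"t{i}" for i in range(arr.shape[0])]
    return rs.CountMatrix(pd.DataFrame(arr, index=idx, columns=samples), read_type)
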