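import numpy as np
import pandas as pd
import pytest

from droneselect.io_formats import GenotypeMatrix, SampleTable


def make_gm(calls, depth=None, populations=None, ploidy=1, chrom="1", positions=None):
    """Small genotype-matrix factory for hand-built fixtures."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    if depth is None:
        depth = np.full((n, L), 10, dtype=np.int32)
    if populations is None:
        populations = ["P1"] * n
    if positions is None:
        positions = np.arange(1, L + 1) * 100
    table = SampleTable.from_records(
        [f"s{i}" for i in range(n)], populations, ploidy=ploidy
    )
    sites = pd.DataFrame(
        {"chrom": str(chrom), "pos": positions, "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(sites, calls, np.asarray(depth, dtype=np.int32), table)


@pytest.fixture
def rng():
    return np.random.default_rng(20160603)


def random_psd_kinship(rng, npop=3, scale=0.08):
    """Random PSD kinship with positive diagonal."""
    A = rng.uniform(-1, 1, size=(npop, npop))
    F = A @ A.T
    F *= scale / np.diag(F).max()
    F += np.eye(npop) * 1e-3
    return F
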