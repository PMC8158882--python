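import numpy as np
import pandas as pd
import pytest

from pheoscan.io_qc import GenotypeMatrix


def make_markers(ids, chrom="1"):
    return pd.DataFrame(
        {
            "marker_id": list(ids),
            "chrom": chrom,
            "pos": np.arange(1, len(ids) + 1) * 1000,
            "allele1": "A",
            "allele2": "C",
        }
    )


def make_gm(dosages, sample_ids=None, marker_ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    sample_ids = sample_ids or [f"s{i:03d}" for i in range(n)]
    marker_ids = marker_ids or [f"m{j:03d}" for j in range(m)]
    return GenotypeMatrix(
        sample_ids=list(sample_ids), markers=make_markers(marker_ids), dosages=dosages
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210527)
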