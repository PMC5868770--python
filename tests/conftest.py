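import numpy as np
import pandas as pd
import pytest

import cnquant as cq


def make_bins(n=200, chrom="1", gc=0.40, coverage=30.0, start=0, bin_size=100,
              mapq=None):
    """Hand-built bin table: ``n`` uniform bins on one chromosome."""
    starts = start + bin_size * np.arange(n)
    df = pd.DataFrame({
        "chrom": chrom,
        "start": starts,
        "end": starts + bin_size,
        "gc": gc,
        "coverage": coverage,
    })
    if mapq is not None:
        df["mapq"] = mapq
    return df


@pytest.fixture(scope="session")
def diploid_result():
    """A fitted model on a noisy flat diploid simulation (2 autosomes)."""
    bins, truth = cq.simulate_genome_bins(
        n_chroms=2, chrom_length=400_000, seed=11,
    )
    return cq.CopyNumberModel(bins).fit(), truth


@pytest.fixture()
def constant_reference():
    """A single accepted GC stratum at 0.40 with copy-neutral coverage 30."""
    table = pd.DataFrame(
        {"mean": [30.0], "count": [100], "accepted": [True]},
        index=pd.Index([0.40], name="gc"),
    )
    return cq.GCReference(table, s_cutoff=50, c_low=10.0, c_high=100.0)
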